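"""Competitive inhibition of Fc-Fc contacts by the staphylococcal protein A
B domain (SpA-B).

SpA-B binds the Fc-Fc interface of an IgG and thereby blocks the homotypic
Fc-Fc contact that drives oligomer growth.  The module tracks the fraction
``phi`` of Fc interfaces left unoccupied by SpA-B and scales the Fc-Fc
association rate by ``phi**2`` (the incoming IgG's interface and the
acceptor oligomer's interface must both be free).  IgG3 interfaces are not
bound by SpA-B; for that subclass ``phi == 1`` regardless of concentration.
"""
from __future__ import annotations

import math

from .params import SpaParameters

__all__ = ["fc_free_fraction", "equilibrium_free_fraction", "scale_fc_association"]


def equilibrium_free_fraction(spa: SpaParameters, spa_conc: float) -> float:
    """Steady-state fraction of SpA-free Fc interfaces, K / (K + [SpA])."""
    if spa_conc < 0:
        raise ValueError("SpA concentration must be non-negative")
    kd = spa.kd
    return kd / (kd + spa_conc)


def fc_free_fraction(
    spa: SpaParameters, spa_conc: float, t: float = math.inf, phi0: float = 1.0
) -> float:
    """Fraction of Fc interfaces unoccupied by SpA-B after time ``t``.

    Solves ``dphi/dt = -kC [SpA] phi + k-C (1 - phi)`` from ``phi(0) = phi0``
    in closed form.  With the default kinetics the relaxation time is about
    one second, so for minutes-long incubations the equilibrium value
    ``K / (K + [SpA])`` is appropriate (``t = inf``, the default).
    """
    if spa_conc < 0:
        raise ValueError("SpA concentration must be non-negative")
    if not 0.0 <= phi0 <= 1.0:
        raise ValueError("phi0 must lie in [0, 1]")
    if spa_conc == 0 and phi0 == 1.0:
        return 1.0
    rate = spa.kC * spa_conc + spa.k_minusC
    phi_eq = spa.k_minusC / rate
    if math.isinf(t):
        return phi_eq
    return phi_eq + (phi0 - phi_eq) * math.exp(-rate * t)


def scale_fc_association(k2: float, phi: float) -> float:
    """Fc-Fc association rate scaled by SpA occupancy: ``k2 * phi**2``."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    return k2 * phi * phi
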