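"""Surface mass-action model of antigen-dependent IgG oligomerization.

The model tracks densities of IgG oligomers growing on an antigenic membrane
through the "vertical" pathway: an IgG binds a surface epitope with one Fab
(state ``y1``), closes a bivalent ring (``y1b``), and the nascent oligomer
then alternates between recruiting a solution IgG through an Fc-Fc contact
(states ``y2b, y4b, ...`` -- newest IgG attached by Fc only) and capturing a
surface epitope with that IgG's free Fab (states ``y3b, y5b, ...``), up to
the epitope-engaged hexamer ``y11b``.

Two compartments couple the surface to the bulk: the surface compartment
(1 um high, instantaneously mixed) exchanges IgG with the bulk at transport
rate ``kT`` and is depleted by binding.  Unbound epitopes can also be
unavailable because they are hidden below bound IgGs; this screening is
encoded by footprint weights ``w_i`` multiplying the growth of each species.

State vector layout (length 14)::

    index  0      1      2 .. 11          12          13
    state  y1     y1b    y2b .. y11b      yIgG_surf   yepi
    unit   um^-2  um^-2  um^-2            M           um^-2
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    SURFACE_COMPARTMENT_ALPHA,
    Condition,
    Protocol,
    RateParameters,
    ScreeningGeometry,
)
from .spa import equilibrium_free_fraction

__all__ = [
    "EffectiveRates",
    "OligomerDistribution",
    "SimulationResult",
    "screening_weights",
    "footprint_areas",
    "effective_rates",
    "ode_rhs",
    "simulate_condition",
    "states_to_distribution",
    "check_reversibility_constraints",
    "implied_lower_branch_rates",
    "N_STATES",
    "IDX_SURF",
    "IDX_EPI",
]

N_STATES = 14
IDX_SURF = 12
IDX_EPI = 13

#: IgG molecules contained in each of the 12 surface species
#: (y1, y1b, y2b..y11b).
_IGG_PER_STATE = np.array([1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6], dtype=float)


@dataclass(frozen=True)
class EffectiveRates:
    """Condition-resolved rate set entering the rate equations."""

    k1: float         # M^-1 s^-1
    k_minus1: float   # s^-1
    k1b: float        # s^-1 um^2
    k2: float         # M^-1 s^-1
    k_minus2: float   # s^-1
    k3: float         # s^-1 um^2
    k4: float         # s^-1 um^2
    kT: float         # s^-1


class OligomerDistribution:
    """Abundances of oligomer sizes 1-6, the observable of the assay."""

    __slots__ = ("abundance",)

    def __init__(self, abundance: Sequence[float]):
        ab = np.asarray(abundance, dtype=float)
        if ab.shape != (6,):
            raise ValueError("abundance must have six entries (sizes 1-6)")
        if np.any(ab < -1e-12 * max(ab.max(initial=0.0), 1.0)):
            raise ValueError("abundances must be non-negative")
        self.abundance = np.clip(ab, 0.0, None)

    @property
    def total_igg_density(self) -> float:
        """IgG molecules per um^2: sum of size x abundance."""
        return float(np.dot(np.arange(1, 7), self.abundance))

    @property
    def total_particles(self) -> float:
        return float(self.abundance.sum())

    @property
    def fractions(self) -> np.ndarray:
        """Fractional abundances (sum to 1; zeros if no particles)."""
        total = self.abundance.sum()
        if total <= 0:
            return np.zeros(6)
        return self.abundance / total

    def __repr__(self) -> str:  # pragma: no cover
        return f"OligomerDistribution({self.abundance.tolist()})"


def footprint_areas(geometry: ScreeningGeometry) -> np.ndarray:
    """Screened areas (um^2) for (monovalent monomer, bivalent monomer,
    dimer, trimer, tetramer, pentamer, hexamer)."""
    for name in ("d1", "gamma", "d2", "delta"):
        if getattr(geometry, name) <= 0:
            raise ValueError(f"geometry parameter {name} must be positive")
    a1m = math.pi * (geometry.d1 / 2.0) ** 2
    a1 = math.pi * (geometry.gamma * geometry.d1 / 2.0) ** 2
    hexagon = math.pi * (geometry.d2 / 2.0) ** 2
    rim = geometry.d2 * geometry.delta
    areas_nm2 = [a1m, a1] + [(i / 6.0) * hexagon + rim for i in (2, 3, 4, 5)] + [hexagon]
    return np.asarray(areas_nm2) * 1e-6  # nm^2 -> um^2


def screening_weights(geometry: ScreeningGeometry, rho_epi: float) -> np.ndarray:
    """Screening weights ``(w1m, w1, w2, ..., w6)``.

    ``w_i = A_i * rho_epi``: the mean number of epitopes hidden beneath the
    footprint of a bound species.  ``w1m`` applies to ``y1``; ``w1`` to
    ``y1b`` and ``y2b``; ``w2``..``w5`` to the successive state pairs; and
    ``w6`` to ``y11b``.
    """
    if rho_epi < 0:
        raise ValueError("epitope density must be non-negative")
    return footprint_areas(geometry) * rho_epi


def effective_rates(params: RateParameters, condition: Condition) -> EffectiveRates:
    """Resolve the surface- and variant-dependent rate set for a condition.

    The epitope-capture rates ``k1b``, ``k3`` and ``k4`` are multiplied by
    the surface prefactor of the condition's DNP fraction; ``k3``/``k4``
    additionally by the E430G factor for mutants.
    """
    a = params.alpha(condition.dnp_fraction)
    nu = params.e430g_factor if condition.mutant else 1.0
    return EffectiveRates(
        k1=params.k1(condition.dnp_fraction),
        k_minus1=params.koff_fab(condition.dnp_fraction),
        k1b=params.k1b * a,
        k2=params.k2,
        k_minus2=params.k_minus2,
        k3=params.k3 * a * nu,
        k4=params.k4 * a * nu,
        kT=params.kT,
    )


def _fluxes(
    y: np.ndarray,
    rates: EffectiveRates,
    c_surf: float,
    phi2: float,
) -> np.ndarray:
    """Net forward fluxes of the 12 transitions along the assembly chain.

    r[0] : solution IgG + epitope -> y1
    r[1] : y1  -> y1b   (ring closure)
    r[2j]: Fc-Fc addition of a solution IgG (even transitions)
    r[2j+1]: epitope capture by the newest IgG (odd transitions)
    """
    k2f = rates.k2 * phi2
    epi = max(y[IDX_EPI], 0.0)
    r = np.empty(12)
    r[0] = rates.k1 * c_surf * epi - rates.k_minus1 * y[0]
    r[1] = rates.k1b * y[0] * epi - 2.0 * rates.k_minus1 * y[1]
    # statistical factor 4: both Fc interfaces of both partners available
    r[2] = 4.0 * k2f * y[1] * c_surf - rates.k_minus2 * y[2]
    r[3] = rates.k3 * y[2] * epi - rates.k_minus1 * y[3]
    for j, src in zip(range(4, 12, 2), range(3, 11, 2)):
        # statistical factor 2: two equivalent Fc-Fc additions onto the
        # open oligomer end
        r[j] = 2.0 * k2f * y[src] * c_surf - rates.k_minus2 * y[j]
        r[j + 1] = rates.k4 * y[j] * epi - rates.k_minus1 * y[j + 1]
    return r


def ode_rhs(
    state: np.ndarray,
    rates: EffectiveRates,
    weights: np.ndarray,
    c_bulk: float,
    fc_free_fraction: float = 1.0,
    alpha_volume: float = SURFACE_COMPARTMENT_ALPHA,
    screening_areas: np.ndarray | None = None,
    validate: bool = True,
) -> np.ndarray:
    """Time derivative of the 14-component state vector.

    ``weights`` are the seven screening weights for 'total'-density
    screening; when ``screening_areas`` is given (free-density screening),
    the weights are recomputed as ``areas * yepi`` at each call.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} entries")
    if validate:
        scale = max(float(np.max(np.abs(y))), 1.0)
        if np.any(y < -1e-9 * scale):
            raise ValueError("state entries must be non-negative")
        if not 0.0 <= fc_free_fraction <= 1.0:
            raise ValueError("fc_free_fraction must lie in [0, 1]")
    c_surf = max(y[IDX_SURF], 0.0)
    r = _fluxes(y, rates, c_surf, fc_free_fraction**2)

    dy = np.empty(N_STATES)
    dy[0] = r[0] - r[1]
    for i in range(1, 11):
        dy[i] = r[i] - r[i + 1]
    dy[11] = r[11]
    # solution-IgG-consuming transitions: initial capture + Fc-Fc additions
    solution_flux = r[0] + r[2] + r[4] + r[6] + r[8] + r[10]
    dy[IDX_SURF] = rates.kT * (c_bulk - y[IDX_SURF]) - alpha_volume * solution_flux
    w = weights if screening_areas is None else screening_areas * max(y[IDX_EPI], 0.0)
    dy[IDX_EPI] = -(
        w[0] * dy[0]
        + w[1] * (dy[1] + dy[2])
        + w[2] * (dy[3] + dy[4])
        + w[3] * (dy[5] + dy[6])
        + w[4] * (dy[7] + dy[8])
        + w[5] * (dy[9] + dy[10])
        + w[6] * dy[11]
    )
    return dy


def states_to_distribution(state: np.ndarray) -> OligomerDistribution:
    """Collapse a state vector into oligomer-size abundances.

    Sizes pair an Fc-attached state with its epitope-engaged successor:
    monomers ``y1 + y1b``, dimers ``y2b + y3b``, ..., hexamers
    ``y10b + y11b``.
    """
    y = np.asarray(state, dtype=float)
    dens = y[:12]
    scale = max(float(dens.max(initial=0.0)), 1.0)
    if np.any(dens < -1e-9 * scale):
        raise ValueError("state densities must be non-negative")
    dens = np.clip(dens, 0.0, None)
    ab = np.array([dens[0] + dens[1]] + [dens[i] + dens[i + 1] for i in range(2, 12, 2)])
    return OligomerDistribution(ab)


@dataclass
class SimulationResult:
    """Full time course and time-averaged observable of one condition."""

    condition: Condition
    times: np.ndarray            # s, concatenated over all phases
    states: np.ndarray           # (14, n_times)
    distribution: OligomerDistribution  # time-averaged over observation
    rates: EffectiveRates
    weights: np.ndarray
    phase_starts: tuple          # start times of (incubation, wash, observe)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[:, -1]


def _integrate_segment(
    y0: np.ndarray,
    duration: float,
    c_bulk: float,
    rates: EffectiveRates,
    weights: np.ndarray,
    phi: float,
    alpha_volume: float,
    areas: np.ndarray | None,
    rtol: float,
    n_eval: int,
) -> tuple[np.ndarray, np.ndarray]:
    if duration <= 0:
        return np.array([0.0]), y0[:, None].copy()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return ode_rhs(
            y, rates, weights, c_bulk, phi,
            alpha_volume=alpha_volume, screening_areas=areas, validate=False,
        )

    atol = np.full(N_STATES, 1e-8)
    atol[IDX_SURF] = 1e-18  # molar scale is ~1e-8
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.0, duration, n_eval),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y


def simulate_condition(
    params: RateParameters,
    condition: Condition,
    protocol: Protocol | None = None,
    geometry: ScreeningGeometry | None = None,
    rtol: float = 1e-8,
    n_average: int = 201,
) -> SimulationResult:
    """Simulate one assay condition and return its oligomer distribution.

    The protocol mimics the experiment: incubation at constant bulk IgG
    concentration, a wash (bulk held by default, optionally zeroed), then
    the bulk set to zero and the system observed for ``t_observe`` with the
    reported distribution time-averaged (trapezoidal, ``n_average`` dense
    points) over that window.
    """
    protocol = protocol or Protocol()
    geometry = geometry or ScreeningGeometry()
    rates = effective_rates(params, condition)
    rho = condition.rho_epi
    weights = screening_weights(geometry, rho)
    areas = footprint_areas(geometry) if geometry.screening == "free" else None

    if condition.spa_conc > 0 and condition.variant != "IgG3":
        phi = equilibrium_free_fraction(params.spa, condition.spa_conc)
    else:
        phi = 1.0

    y0 = np.zeros(N_STATES)
    y0[IDX_EPI] = rho

    wash_bulk = condition.c_bulk if protocol.wash_bulk == "hold" else 0.0
    segments = [
        (condition.t_incubation, condition.c_bulk, max(2, n_average // 4)),
        (protocol.t_wash, wash_bulk, max(2, n_average // 4)),
        (protocol.t_observe, 0.0, n_average),
    ]

    times_list, states_list, phase_starts = [], [], []
    t0, y = 0.0, y0
    for duration, c_bulk, n_eval in segments:
        phase_starts.append(t0)
        t, ys = _integrate_segment(
            y, duration, c_bulk, rates, weights, phi,
            geometry.alpha_volume, areas, rtol, n_eval,
        )
        times_list.append(t + t0)
        states_list.append(ys)
        t0 += duration
        y = ys[:, -1].copy()

    times = np.concatenate(times_list)
    states = np.concatenate(states_list, axis=1)

    if np.min(states[IDX_EPI]) < -1e-6 * rho:
        raise RuntimeError(
            "epitope bookkeeping went negative beyond tolerance "
            f"(min yepi = {np.min(states[IDX_EPI]):.3g} um^-2)"
        )
    if np.min(states[IDX_EPI]) < 1e-9 * rho:
        warnings.warn(
            "available epitope density approached zero; screening clamped",
            RuntimeWarning,
            stacklevel=2,
        )

    obs_t, obs_y = times_list[-1], states_list[-1]
    if protocol.averaging and protocol.t_observe > 0:
        span = obs_t[-1] - obs_t[0]
        avg_state = np.trapezoid(obs_y, obs_t, axis=1) / span
    else:
        avg_state = obs_y[:, -1]
    distribution = states_to_distribution(np.clip(avg_state, 0.0, None))

    return SimulationResult(
        condition=condition,
        times=times,
        states=states,
        distribution=distribution,
        rates=rates,
        weights=weights,
        phase_starts=tuple(phase_starts),
    )


# ---------------------------------------------------------------------------
# Microscopic-reversibility constraints linking the (out-of-scope) lower
# assembly branch to the upper one.  Provided as a configuration checker for
# future extensions; the fitted model never populates these states.
# ---------------------------------------------------------------------------

def implied_lower_branch_rates(full_params: Mapping[str, float]) -> dict[str, float]:
    """Ring-closure rates of the lower branch implied by path independence:
    ``k1b_i = k1b * (k3 / k3_star) * (k4 / k4_star)**(i - 2)`` for i = 2..5.
    """
    p = full_params
    for key in ("k1b", "k3", "k3_star", "k4", "k4_star"):
        if p.get(key, 0.0) <= 0:
            raise ValueError(f"rate {key} must be provided and positive")
    base = p["k1b"] * p["k3"] / p["k3_star"]
    ratio = p["k4"] / p["k4_star"]
    return {f"k1b_{i}": base * ratio ** (i - 2) for i in range(2, 6)}


def check_reversibility_constraints(full_params: Mapping[str, float]) -> np.ndarray:
    """Log-space residuals of the detailed-balance constraints.

    An all-zero vector means Gibbs free energy accumulates path-independently
    around every cycle connecting the two assembly branches.  Expected keys:
    ``k1b, k3, k3_star, k4, k4_star, k1b_2 .. k1b_5`` (optionally ``k1b_6``)
    and ``k5, k6, k7`` for the hexamer-closure cycle.
    """
    p = dict(full_params)
    for key, value in p.items():
        if value <= 0:
            raise ValueError(f"rate {key} must be positive, got {value}")
    residuals = []
    # cycle through the first ring closure: k1b k3 = k1b_2 k3*
    residuals.append(
        math.log(p["k1b"] * p["k3"]) - math.log(p["k1b_2"] * p["k3_star"])
    )
    # successive cycles: k1b_i k4 = k1b_{i+1} k4*
    for i in range(2, 6):
        lo, hi = f"k1b_{i}", f"k1b_{i + 1}"
        if hi not in p:
            break
        residuals.append(
            math.log(p[lo] * p["k4"]) - math.log(p[hi] * p["k4_star"])
        )
    # hexamer closure cycle: k5 k7 = k6 k4*
    if all(k in p for k in ("k5", "k6", "k7")):
        residuals.append(
            math.log(p["k5"] * p["k7"]) - math.log(p["k6"] * p["k4_star"])
        )
    return np.asarray(residuals)
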