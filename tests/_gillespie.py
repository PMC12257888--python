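"""Exact stochastic simulation (SSA) oracle for the oligomerization network.

Independent of the ODE implementation: the reaction network is re-derived
here as integer molecule counts on a membrane patch of area ``A`` um^2 with
its own 1-um-high solution column.  Transport appears as a birth-death
process on the solution molecule count; screening is continuous
bookkeeping of the free-epitope density.  All propensities are constant
between events, so the plain Gillespie direct method is exact.
"""
from __future__ import annotations

import math
import random

from oligokin.model import effective_rates, screening_weights
from oligokin.params import SURFACE_COMPARTMENT_ALPHA, Condition, RateParameters, ScreeningGeometry


def gillespie_final_counts(
    params: RateParameters,
    condition: Condition,
    t_end: float,
    area: float = 1.0,
    seed: int = 0,
    phi: float = 1.0,
) -> list[int]:
    """Surface-state molecule counts (y1, y1b, y2b..y11b) at ``t_end``."""
    r = effective_rates(params, condition)
    geom = ScreeningGeometry()
    w = screening_weights(geom, condition.rho_epi)
    alpha_v = SURFACE_COMPARTMENT_ALPHA
    rho = condition.rho_epi
    c_bulk = condition.c_bulk
    phi2 = phi * phi

    rng = random.Random(seed)
    n = [0] * 12          # surface species counts on the patch
    m = 0                 # solution-compartment molecules above the patch
    t = 0.0

    inflow = r.kT * (c_bulk / alpha_v) * area  # molecules / s

    while True:
        epi = rho - (
            w[0] * n[0]
            + w[1] * (n[1] + n[2])
            + w[2] * (n[3] + n[4])
            + w[3] * (n[5] + n[6])
            + w[4] * (n[7] + n[8])
            + w[5] * (n[9] + n[10])
            + w[6] * n[11]
        ) / area
        if epi < 0.0:
            epi = 0.0
        y = m * alpha_v / area  # molarity in the patch column

        # (propensity, solution-molecule change, from-state, to-state)
        events = [
            (inflow, +1, -1, -1),
            (r.kT * m, -1, -1, -1),
            (r.k1 * y * epi * area, -1, -1, 0),   # solution -> y1
            (r.k_minus1 * n[0], +1, 0, -1),       # y1 -> solution
            (r.k1b * epi * n[0], 0, 0, 1),        # ring closure
            (2.0 * r.k_minus1 * n[1], 0, 1, 0),
            (4.0 * r.k2 * phi2 * y * n[1], -1, 1, 2),
            (r.k_minus2 * n[2], +1, 2, 1),
            (r.k3 * epi * n[2], 0, 2, 3),
            (r.k_minus1 * n[3], 0, 3, 2),
        ]
        for j in range(4, 12, 2):
            events.append((2.0 * r.k2 * phi2 * y * n[j - 1], -1, j - 1, j))
            events.append((r.k_minus2 * n[j], +1, j, j - 1))
            events.append((r.k4 * epi * n[j], 0, j, j + 1))
            events.append((r.k_minus1 * n[j + 1], 0, j + 1, j))

        total = sum(e[0] for e in events)
        if total <= 0.0:
            break
        t += rng.expovariate(total)
        if t >= t_end:
            break
        pick = rng.random() * total
        acc = 0.0
        for a, dm, src, dst in events:
            acc += a
            if pick <= acc:
                m += dm
                if src >= 0:
                    n[src] -= 1
                if dst >= 0:
                    n[dst] += 1
                break
    return n


def counts_to_size_fractions(n: list[int]) -> list[float]:
    sizes = [n[0] + n[1]] + [n[i] + n[i + 1] for i in range(2, 12, 2)]
    total = sum(sizes)
    if total == 0:
        return [0.0] * 6
    return [s / total for s in sizes]


def mean_fractions(
    params: RateParameters,
    condition: Condition,
    t_end: float,
    n_replicates: int,
    area: float = 1.0,
    seed: int = 0,
):
    """Replicate means and standard errors of the size fractions, pooling
    particles within each replicate."""
    per_rep = [
        counts_to_size_fractions(
            gillespie_final_counts(params, condition, t_end, area, seed=seed + i)
        )
        for i in range(n_replicates)
    ]
    means = [sum(rep[s] for rep in per_rep) / n_replicates for s in range(6)]
    ses = [
        math.sqrt(
            sum((rep[s] - means[s]) ** 2 for rep in per_rep)
            / (n_replicates - 1)
            / n_replicates
        )
        for s in range(6)
    ]
    return means, ses
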