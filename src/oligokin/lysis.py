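"""Complement-dependent liposome lysis predicted from IgG oligomerization.

Chains the surface oligomerization model through a configurable C1-binding
layer and a Poisson single-hit lysis model: oligomer distributions on the
vesicle surface determine the density of C1 bound to C1-activating
oligomers (tetramers and larger); each bound, activated C1 is assumed to
nucleate at least one membrane attack complex; pores are Poisson
distributed over vesicles, and a vesicle lyses once it carries at least
``lysis_threshold`` pores.  Scanning the IgG concentration yields sigmoid
lysis curves and their EC50.

The C1 layer uses independent per-oligomer-size 1:1 binding kinetics whose
rate constants are configuration inputs, not outputs of this package; the
bundled defaults are synthetic placeholders of plausible magnitude.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import OligomerDistribution, simulate_condition
from .params import Condition, Protocol, RateParameters, ScreeningGeometry

__all__ = [
    "C1Parameters",
    "VesicleModel",
    "c1_bound_density",
    "lysis_fraction",
    "lysis_curve",
]

#: Oligomer sizes able to activate C1.
ACTIVATING_SIZES = (4, 5, 6)


@dataclass(frozen=True)
class C1Parameters:
    """1:1 C1 binding kinetics per activating oligomer size.

    Rates are consumed as configuration; the defaults are synthetic
    placeholders (avidity increasing with oligomer size) and should be
    replaced with measured values where available.
    """

    kon_c1: Mapping[int, float] = field(
        default_factory=lambda: {4: 2.0e6, 5: 2.0e6, 6: 2.0e6}
    )
    koff_c1: Mapping[int, float] = field(
        default_factory=lambda: {4: 2.0e-2, 5: 5.0e-3, 6: 1.0e-3}
    )
    c1_conc: float = 1.0e-9  # M

    def __post_init__(self) -> None:
        for size in ACTIVATING_SIZES:
            if size not in self.kon_c1 or size not in self.koff_c1:
                raise KeyError(
                    f"C1 kinetics missing for activating oligomer size {size}"
                )
        if any(v <= 0 for v in self.kon_c1.values()) or any(
            v <= 0 for v in self.koff_c1.values()
        ):
            raise ValueError("C1 rate constants must be strictly positive")
        if any(s < min(ACTIVATING_SIZES) for s in self.kon_c1):
            raise ValueError("oligomers smaller than tetramers do not bind C1")
        if self.c1_conc < 0:
            raise ValueError("C1 concentration must be non-negative")

    def occupancy(self, size: int, t: float = math.inf) -> float:
        """1:1 binding-site occupancy of size-``size`` oligomers at time t."""
        kon, koff = self.kon_c1[size], self.koff_c1[size]
        theta_ss = self.c1_conc / (self.c1_conc + koff / kon)
        if math.isinf(t):
            return theta_ss
        return theta_ss * (1.0 - math.exp(-(kon * self.c1_conc + koff) * t))


@dataclass(frozen=True)
class VesicleModel:
    diameter: float = 200.0    # nm
    lysis_threshold: int = 1   # MAC pores needed to lyse a vesicle

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("vesicle diameter must be positive")
        if self.lysis_threshold < 1 or int(self.lysis_threshold) != self.lysis_threshold:
            raise ValueError("lysis threshold must be a positive integer")

    @property
    def surface_area(self) -> float:
        """Vesicle surface area in um^2."""
        radius_um = self.diameter / 2.0 * 1e-3
        return 4.0 * math.pi * radius_um**2


def c1_bound_density(
    distribution: OligomerDistribution,
    c1: C1Parameters,
    t: float = math.inf,
) -> float:
    """Surface density (um^-2) of C1 bound to activating oligomers.

    Each tetramer-or-larger oligomer carries one C1 site filled with the
    1:1 occupancy at the C1 concentration (steady state at ``t = inf``);
    every bound C1 is assumed to give rise to at least one MAC.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    total = 0.0
    for size in ACTIVATING_SIZES:
        total += c1.occupancy(size, t) * distribution.abundance[size - 1]
    return total


def lysis_fraction(c1_density: float, vesicle: VesicleModel) -> float:
    """Fraction of vesicles lysed for a C1 (= MAC) surface density.

    Pores per vesicle are Poisson with mean ``lambda = density x area``;
    lysis requires at least ``lysis_threshold`` pores, i.e. the Poisson
    upper tail (``1 - exp(-lambda)`` for the single-hit threshold).
    """
    if c1_density < 0:
        raise ValueError("C1 density must be non-negative")
    lam = c1_density * vesicle.surface_area
    return float(stats.poisson.sf(vesicle.lysis_threshold - 1, lam))


def _interp_ec50(concs: np.ndarray, lysis: np.ndarray) -> float:
    """EC50 by monotone piecewise-linear interpolation in log concentration."""
    envelope = np.maximum.accumulate(lysis)
    above = np.nonzero(envelope >= 0.5)[0]
    if above.size == 0:
        return math.nan
    j = above[0]
    if j == 0:
        return float(concs[0])
    x0, x1 = math.log(concs[j - 1]), math.log(concs[j])
    y0, y1 = envelope[j - 1], envelope[j]
    if y1 == y0:
        return float(concs[j])
    return math.exp(x0 + (0.5 - y0) / (y1 - y0) * (x1 - x0))


def lysis_curve(
    params: RateParameters,
    c1: C1Parameters,
    vesicle: VesicleModel,
    conc_grid: Sequence[float],
    condition_template: Condition,
    protocol: Protocol | None = None,
    geometry: ScreeningGeometry | None = None,
    sim_rtol: float = 1e-8,
) -> tuple[pd.DataFrame, float]:
    """Lysis versus IgG concentration for one antibody/surface scenario.

    For each concentration the full oligomerization protocol is run on the
    vesicle's antigen surface (planar model; curvature neglected), C1 is
    loaded onto activating oligomers, and the Poisson single-hit model
    converts pore density to a lysed fraction.  Returns a per-concentration
    diagnostics table and the EC50 (NaN, flagged by the caller, if 50%
    lysis is never reached).

    Table columns: lysis fraction, C1 per vesicle, total IgG per vesicle,
    size fractions 1-6, and C1 recruitment efficiency (bound C1 per
    surface-bound IgG).
    """
    concs = np.asarray(conc_grid, dtype=float)
    if np.any(concs < 0) or concs.size < 2 or np.any(np.diff(concs) <= 0):
        raise ValueError("conc_grid must be non-negative and strictly increasing")

    rows = []
    for c in concs:
        if c == 0.0:
            dist = OligomerDistribution(np.zeros(6))
        else:
            cond = Condition(
                variant=condition_template.variant,
                mutant=condition_template.mutant,
                c_bulk=float(c),
                dnp_fraction=condition_template.dnp_fraction,
                t_incubation=condition_template.t_incubation,
                spa_conc=condition_template.spa_conc,
            )
            dist = simulate_condition(
                params, cond, protocol=protocol, geometry=geometry, rtol=sim_rtol
            ).distribution
        density_c1 = c1_bound_density(dist, c1)
        area = vesicle.surface_area
        total_igg = dist.total_igg_density
        row = {
            "c_bulk_M": float(c),
            "lysis_fraction": lysis_fraction(density_c1, vesicle),
            "c1_per_vesicle": density_c1 * area,
            "igg_per_vesicle": total_igg * area,
            "c1_recruitment_efficiency": (
                density_c1 / total_igg if total_igg > 0 else 0.0
            ),
        }
        fr = dist.fractions
        for s in range(6):
            row[f"fraction_size_{s + 1}"] = float(fr[s])
        rows.append(row)

    table = pd.DataFrame(rows)
    positive = table["c_bulk_M"].to_numpy() > 0
    ec50 = _interp_ec50(
        table.loc[positive, "c_bulk_M"].to_numpy(),
        table.loc[positive, "lysis_fraction"].to_numpy(),
    )
    return table, ec50
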