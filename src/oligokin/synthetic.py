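"""Synthetic data generation with the statistical structure of the assays.

Provides forward-simulated oligomer-count tables (multinomial particle
sampling, emulating single-particle counting on membrane patches),
rupture-force event tables, and biosensor traces, so that every analysis
in the package can be exercised and validated without measured data.
All generators are bit-reproducible under a seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .biosensor import BindingTrace, Schedule, langmuir_simulate
from .forcespec import BellEvansParams, simulate_rupture_events
from .model import OligomerDistribution, simulate_condition
from .params import Condition, Protocol, RateParameters, ScreeningGeometry, dnp_density

__all__ = [
    "FixtureSpec",
    "default_conditions",
    "figure4_conditions",
    "dnp_density",
    "sample_distribution_counts",
    "generate_dataset",
    "generate_fd_events",
    "generate_gci_traces",
]


def figure4_conditions(variant: str = "IgG1", mutant: bool = False) -> list[Condition]:
    """The nine concentration x surface-density conditions of the core
    oligomer-distribution experiment: 6.6, 16.5 and 33 nM IgG on 0.85, 2.5
    and 5% DNP surfaces, 3 min incubation."""
    return [
        Condition(
            variant=variant,
            mutant=mutant,
            c_bulk=c * 1e-9,
            dnp_fraction=frac,
            t_incubation=180.0,
        )
        for frac in (0.0085, 0.025, 0.05)
        for c in (6.6, 16.5, 33.0)
    ]


def default_conditions() -> list[Condition]:
    """Reconstructed 35-condition design of the IgG1 calibration dataset.

    The published design is not tabulated; this reconstruction follows the
    reported structure: concentration x surface grids for wild type and
    E430G, incubation-time series for both, and an SpA titration.
    """
    conditions = figure4_conditions("IgG1", mutant=False)
    conditions += figure4_conditions("IgG1", mutant=True)
    for mutant in (False, True):
        for t_inc in (30.0, 60.0, 120.0, 300.0, 600.0, 1200.0):
            conditions.append(
                Condition(
                    variant="IgG1",
                    mutant=mutant,
                    c_bulk=16.5e-9,
                    dnp_fraction=0.05,
                    t_incubation=t_inc,
                )
            )
    for spa_um in (0.045, 0.15, 0.45, 1.5, 4.5):
        conditions.append(
            Condition(
                variant="IgG1",
                mutant=False,
                c_bulk=33e-9,
                dnp_fraction=0.05,
                t_incubation=180.0,
                spa_conc=spa_um * 1e-6,
            )
        )
    assert len(conditions) == 35
    return conditions


@dataclass(frozen=True)
class FixtureSpec:
    """Design of a synthetic oligomer-distribution dataset."""

    conditions: Sequence[Condition] = field(default_factory=default_conditions)
    n_particles: int = 300        # expected observed particles per condition
    #: 'multinomial' fixes the particle total per condition (fractions only);
    #: 'poisson' counts particles in a scanned area sized to an expected
    #: total of n_particles, keeping the absolute-density information;
    #: 'none' writes rounded expected counts.
    noise: str = "multinomial"
    seed: int = 0
    protocol: Protocol = field(default_factory=Protocol)
    geometry: ScreeningGeometry = field(default_factory=ScreeningGeometry)
    sim_rtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be non-negative")
        if self.noise not in ("multinomial", "poisson", "none"):
            raise ValueError("noise must be 'multinomial', 'poisson' or 'none'")


def sample_distribution_counts(
    distribution: OligomerDistribution,
    n_particles: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Multinomial particle counts over oligomer sizes 1-6."""
    if n_particles < 0:
        raise ValueError("n_particles must be non-negative")
    if n_particles == 0:
        return np.zeros(6, dtype=np.int64)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.multinomial(n_particles, distribution.fractions)


def _condition_row(cid: str, cond: Condition) -> dict:
    return {
        "condition_id": cid,
        "variant": cond.variant,
        "mutant": "E430G" if cond.mutant else "WT",
        "c_bulk_nM": cond.c_bulk * 1e9,
        "dnp_fraction": cond.dnp_fraction,
        "t_incubation_s": cond.t_incubation,
        "spa_conc_uM": cond.spa_conc * 1e6,
    }


def generate_dataset(
    params: RateParameters,
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Forward-simulate a full synthetic dataset.

    Returns ``(condition_table, count_table, truth)`` where the tables use
    the package's CSV schemas and ``truth`` records the generating
    parameters and the exact model fractions per condition for recovery
    assertions.  Counts are multinomial draws over a fixed particle total,
    Poisson draws over a fixed scanned area (recorded in the count table's
    ``area_um2`` column), or rounded expectations with ``noise='none'``;
    all reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cond_rows, count_rows = [], []
    truth_fractions = {}
    for i, cond in enumerate(spec.conditions):
        cid = f"c{i + 1:02d}"
        try:
            sim = simulate_condition(
                params, cond,
                protocol=spec.protocol, geometry=spec.geometry, rtol=spec.sim_rtol,
            )
        except Exception as exc:
            raise RuntimeError(f"simulation failed for condition {cid}: {exc}") from exc
        fractions = sim.distribution.fractions
        truth_fractions[cid] = fractions.tolist()
        area = float("nan")
        if spec.noise == "multinomial":
            counts = sample_distribution_counts(sim.distribution, spec.n_particles, rng)
        elif spec.noise == "poisson":
            total = sim.distribution.total_particles
            if total <= 0:
                raise RuntimeError(f"condition {cid} produced no particles")
            area = spec.n_particles / total
            counts = rng.poisson(area * sim.distribution.abundance)
        else:
            counts = np.rint(fractions * spec.n_particles).astype(np.int64)
        cond_rows.append(_condition_row(cid, cond))
        row = {
            "condition_id": cid,
            **{f"size_{s + 1}": int(counts[s]) for s in range(6)},
        }
        if spec.noise == "poisson":
            row["area_um2"] = area
        count_rows.append(row)
    truth = {
        "parameters": {
            "k1b": params.k1b,
            "k2": params.k2,
            "k_minus2": params.k_minus2,
            "k3": params.k3,
            "k4": params.k4,
            "kT": params.kT,
            "e430g_factor": params.e430g_factor,
            "alpha_prefactors": {str(k): v for k, v in params.alpha_prefactors.items()},
        },
        "n_particles": spec.n_particles,
        "noise": spec.noise,
        "seed": spec.seed,
        "fractions": truth_fractions,
    }
    return pd.DataFrame(cond_rows), pd.DataFrame(count_rows), truth


def generate_fd_events(
    params: BellEvansParams,
    loading_rates: Sequence[float],
    n_per_rate: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rupture-event table (one row per event) across loading rates."""
    rng = np.random.default_rng(seed)
    frames = []
    for r in loading_rates:
        forces = simulate_rupture_events(
            params, r, n_per_rate, seed=int(rng.integers(2**31))
        )
        frames.append(
            pd.DataFrame({"loading_rate_pN_s": r, "force_pN": forces})
        )
    return pd.concat(frames, ignore_index=True)


def generate_gci_traces(
    kon: float,
    koff: float,
    rmax: float,
    concentrations: Sequence[float],
    schedule: Schedule | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 301,
) -> list[BindingTrace]:
    """Langmuir concentration series with optional Gaussian response noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    traces = []
    for conc in concentrations:
        trace = langmuir_simulate(kon, koff, rmax, conc, schedule, n_points)
        if noise_sd > 0:
            trace = BindingTrace(
                times=trace.times,
                response=trace.response + rng.normal(0.0, noise_sd, trace.times.shape),
                analyte_conc=trace.analyte_conc,
                t_association_end=trace.t_association_end,
            )
        traces.append(trace)
    return traces
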