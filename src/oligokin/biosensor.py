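"""Simulation and global fitting of 1:1 Langmuir biosensor kinetics.

Models label-free binding traces of a Fab concentration series to an
antigen surface.  During association at analyte concentration ``C`` the
response follows ``R(t) = R_eq (1 - exp(-(kon C + koff) t))`` with
``R_eq = Rmax C / (C + KD)``, ``KD = koff / kon``; dissociation decays
exponentially at ``koff`` from the association endpoint.  The global fit
shares ``kon``, ``koff`` and ``Rmax`` across all traces of the series.
Mass transport is deliberately not modelled here: the two-compartment
treatment is reserved for the oligomerization system.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "BindingTrace",
    "Schedule",
    "langmuir_response",
    "langmuir_simulate",
    "langmuir_fit_global",
    "subtract_baseline",
]


@dataclass(frozen=True)
class Schedule:
    """Association / dissociation phase durations (defaults: 2.5 min on,
    25 min off)."""

    t_association: float = 150.0   # s
    t_dissociation: float = 1500.0  # s

    def __post_init__(self) -> None:
        if self.t_association <= 0 or self.t_dissociation < 0:
            raise ValueError("phase durations must be positive")


@dataclass(frozen=True)
class BindingTrace:
    """One biosensor time-response trace at a single analyte concentration."""

    times: np.ndarray        # s, from injection start
    response: np.ndarray     # response units
    analyte_conc: float      # M
    t_association_end: float  # s, association -> dissociation boundary

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "response", r)
        if t.ndim != 1 or r.shape != t.shape:
            raise ValueError("times and response must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("response must be finite")
        if self.analyte_conc < 0:
            raise ValueError("analyte concentration must be non-negative")
        if not 0 < self.t_association_end <= t[-1] + 1e-9:
            raise ValueError("association end must fall inside the trace")


def langmuir_response(
    times: np.ndarray,
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    t_association_end: float,
) -> np.ndarray:
    """Closed-form 1:1 Langmuir response over association + dissociation."""
    t = np.asarray(times, dtype=float)
    if min(kon, koff, rmax) <= 0:
        raise ValueError("kon, koff and rmax must be strictly positive")
    if conc < 0:
        raise ValueError("analyte concentration must be non-negative")
    if conc == 0:
        return np.zeros_like(t)
    kobs = kon * conc + koff
    r_eq = rmax * conc / (conc + koff / kon)
    assoc = r_eq * (1.0 - np.exp(-kobs * np.minimum(t, t_association_end)))
    r_end = r_eq * (1.0 - math.exp(-kobs * t_association_end))
    dissoc = r_end * np.exp(-koff * np.clip(t - t_association_end, 0.0, None))
    return np.where(t <= t_association_end, assoc, dissoc)


def langmuir_simulate(
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    schedule: Schedule | None = None,
    n_points: int = 301,
) -> BindingTrace:
    """Generate a noiseless 1:1 Langmuir trace for one analyte concentration.

    The association/dissociation boundary is always a sample point so that
    the phase structure survives a CSV round trip exactly.
    """
    schedule = schedule or Schedule()
    t_end = schedule.t_association + schedule.t_dissociation
    n_assoc = max(2, round(n_points * schedule.t_association / t_end))
    n_diss = max(2, n_points - n_assoc + 1)
    times = np.concatenate([
        np.linspace(0.0, schedule.t_association, n_assoc),
        np.linspace(schedule.t_association, t_end, n_diss)[1:],
    ])
    response = langmuir_response(
        times, kon, koff, rmax, conc, schedule.t_association
    )
    return BindingTrace(
        times=times,
        response=response,
        analyte_conc=conc,
        t_association_end=schedule.t_association,
    )


def subtract_baseline(trace: BindingTrace, t_baseline: float) -> BindingTrace:
    """Linear-baseline correction from the pre-association window
    ``[0, t_baseline]`` (blank/reference subtraction is assumed upstream)."""
    mask = trace.times <= t_baseline
    if mask.sum() < 2:
        raise ValueError("baseline window contains fewer than two samples")
    slope, intercept = np.polyfit(trace.times[mask], trace.response[mask], 1)
    corrected = trace.response - (slope * trace.times + intercept)
    return BindingTrace(
        times=trace.times,
        response=corrected,
        analyte_conc=trace.analyte_conc,
        t_association_end=trace.t_association_end,
    )


def langmuir_fit_global(
    traces: list[BindingTrace],
    initial: tuple[float, float, float] | None = None,
    ci: bool = True,
) -> dict:
    """Global least-squares 1:1 Langmuir fit sharing (kon, koff, Rmax).

    Optimizes in log10 space with a trust-region least-squares solver.
    Returns a dict with ``kon``, ``koff``, ``rmax``, ``kd``, per-parameter
    Wald 95% intervals from the Jacobian at the optimum, and diagnostics.
    A practically unbounded ``rmax`` (all concentrations far below KD) is
    flagged via ``rmax_identifiable``.
    """
    if not traces:
        raise ValueError("at least one trace is required")
    concs = np.array([tr.analyte_conc for tr in traces])
    if np.all(concs == 0):
        raise ValueError("all traces have zero analyte concentration")

    rmax0 = max(float(tr.response.max()) for tr in traces) or 1.0
    if initial is None:
        # rate constants are unknown a priori; scan a coarse grid of starts
        starts = [
            (kon0, koff0, 1.5 * rmax0)
            for kon0 in (1e3, 1e4, 1e5, 1e6)
            for koff0 in (1e-3, 1e-2, 1e-1, 1.0)
        ]
    else:
        starts = [tuple(initial)]

    def residuals(x_log: np.ndarray) -> np.ndarray:
        kon, koff, rmax = 10.0 ** x_log
        res = [
            langmuir_response(
                tr.times, kon, koff, rmax, tr.analyte_conc, tr.t_association_end
            )
            - tr.response
            for tr in traces
        ]
        return np.concatenate(res)

    sol = None
    for start in starts:
        x0 = np.log10(np.asarray(start, dtype=float))
        candidate = least_squares(
            residuals, x0, method="trf",
            bounds=(x0 - 12.0, x0 + 12.0), xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if sol is None or candidate.cost < sol.cost:
            sol = candidate
    kon, koff, rmax = 10.0 ** sol.x
    n_obs = sum(len(tr.times) for tr in traces)
    dof = max(n_obs - 3, 1)
    s2 = 2.0 * sol.cost / dof

    out = {
        "kon": kon,
        "koff": koff,
        "rmax": rmax,
        "kd": koff / kon,
        "sse": 2.0 * sol.cost,
        "success": bool(sol.success),
        "n_observations": n_obs,
    }
    if ci:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            sd_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            sd_log = np.full(3, np.inf)
        tq = stats.t.ppf(0.975, dof)
        for i, name in enumerate(("kon", "koff", "rmax")):
            est = out[name]
            if np.isfinite(sd_log[i]):
                half = tq * sd_log[i]
                out[f"{name}_ci95"] = (est * 10.0 ** -half, est * 10.0 ** half)
            else:
                out[f"{name}_ci95"] = (float("nan"), float("nan"))
        # Rmax is informed only when some concentration approaches KD
        out["rmax_identifiable"] = bool(
            np.max(concs) >= 0.1 * out["kd"] and np.isfinite(sd_log[2])
            and sd_log[2] < 1.0
        )
    return out
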