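"""Global weighted least-squares fitting of the oligomerization model to
multi-condition oligomer-size distributions, with profile-likelihood
confidence intervals.

Parameters are optimized in log10 space (all rates are positive and span
orders of magnitude) with Nelder-Mead and optional seeded multi-starts.
Confidence intervals follow the profile-likelihood construction: one
parameter is scanned on a log grid, the others are re-optimized, and the
interval boundary is where the objective crosses
``f_best * (1 + F(0.95; 1, n - p) / (n - p))``.  An upper or lower bound
that never crosses within the scan range is reported open (``inf``/``0``)
and flagged, mirroring practically non-identifiable directions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import f as f_dist

from .model import OligomerDistribution, simulate_condition
from .params import Condition, Protocol, RateParameters, ScreeningGeometry

__all__ = [
    "FitSpec",
    "FitResult",
    "objective",
    "fit",
    "profile_ci",
    "minimize_log",
    "profile_interval",
]

Dataset = Sequence[tuple[Condition, OligomerDistribution]]


@dataclass(frozen=True)
class FitSpec:
    """What to fit: free parameters, their starts/bounds, and weighting.

    Free parameters are addressed by :meth:`RateParameters.updated` names
    (e.g. ``"k1b"``, ``"k3"``, ``"kon_fab.0.025"``, ``"e430g_factor"``).
    Bounds are in natural units; optimization happens in log10 space.
    """

    free: Mapping[str, float]                      # name -> initial value
    baseline: RateParameters = field(default_factory=RateParameters)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    kind: str = "ls"    # 'ls' (fractions), 'multinomial' or 'poisson' (counts)
    #: per-condition scanned areas (um^2) for the 'poisson' objective, which
    #: compares absolute particle counts (density x area) and therefore uses
    #: the total-density information that fractions discard
    areas: Sequence[float] | None = None
    n_starts: int = 1
    seed: int | None = None
    start_spread: float = math.log10(3.0)  # multi-start jitter, log10 units
    protocol: Protocol = field(default_factory=Protocol)
    geometry: ScreeningGeometry = field(default_factory=ScreeningGeometry)
    sim_rtol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        for name, (lo, hi) in self.bounds.items():
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {name} must satisfy 0 < lo < hi")
        if any(v <= 0 for v in self.free.values()):
            raise ValueError("initial values must be positive")
        if self.kind not in ("ls", "multinomial", "poisson"):
            raise ValueError("kind must be 'ls', 'multinomial' or 'poisson'")
        if self.kind == "poisson" and self.areas is None:
            raise ValueError("the 'poisson' objective needs per-condition areas")

    @property
    def names(self) -> list[str]:
        return list(self.free)


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float
    ci95: dict[str, tuple[float, float]]
    covariance_proxy: np.ndarray      # log10-space covariance estimate
    convergence: dict
    n_observations: int

    @property
    def success(self) -> bool:
        return bool(self.convergence.get("success", False))


def _apply(spec: FitSpec, values: Mapping[str, float]) -> RateParameters:
    return spec.baseline.updated(**dict(values))


def objective(
    params: RateParameters,
    dataset: Dataset,
    kind: str = "ls",
    protocol: Protocol | None = None,
    geometry: ScreeningGeometry | None = None,
    sim_rtol: float = 1e-6,
    areas: Sequence[float] | None = None,
) -> float:
    """Goodness-of-fit of a parameter set against observed distributions.

    ``'ls'``: sum over conditions and sizes of squared differences between
    model and observed fractional abundances (equal per-condition weights).
    ``'multinomial'``: twice the negative multinomial log-likelihood of the
    observed counts under the model fractions (up to the data-only term).
    ``'poisson'``: Poisson deviance of the observed counts against model
    density x scanned area (``areas``, um^2, one per condition); unlike the
    fraction-based objectives this uses the absolute-density information,
    which is what identifies the overall scale of the capture rates.
    """
    if kind == "poisson":
        if areas is None or len(areas) != len(dataset):
            raise ValueError("'poisson' objective needs one area per condition")
    total = 0.0
    for i, (cond, observed) in enumerate(dataset):
        try:
            sim = simulate_condition(
                params, cond, protocol=protocol, geometry=geometry, rtol=sim_rtol
            )
        except Exception as exc:
            raise RuntimeError(f"simulation failed for condition {cond}: {exc}") from exc
        if kind == "ls":
            f_model = sim.distribution.fractions
            total += float(np.sum((f_model - observed.fractions) ** 2))
        elif kind == "multinomial":
            f_model = sim.distribution.fractions
            counts = observed.abundance
            with np.errstate(divide="ignore"):
                logf = np.log(np.clip(f_model, 1e-300, None))
            total += float(-2.0 * np.sum(counts * logf))
        else:  # poisson deviance, zero-safe
            counts = observed.abundance
            mu = np.clip(areas[i] * sim.distribution.abundance, 1e-300, None)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(
                    counts > 0, counts * np.log(counts / mu) - counts + mu, mu
                )
            total += float(2.0 * np.sum(term))
    return total


def minimize_log(
    fun: Callable[[np.ndarray], float],
    x0_log: np.ndarray,
    bounds_log: Sequence[tuple[float, float]] | None = None,
    n_starts: int = 1,
    seed: int | None = None,
    spread: float = math.log10(3.0),
    xatol: float = 1e-3,
    fatol: float | None = None,
    maxiter: int | None = None,
) -> tuple[np.ndarray, float, dict]:
    """Nelder-Mead in log10-parameter space with seeded multi-starts.

    ``fatol=None`` scales the function tolerance to the starting objective;
    parameter precision is governed by ``xatol`` (both criteria must hold
    simultaneously for Nelder-Mead to stop).
    """

    def clipped(x: np.ndarray) -> np.ndarray:
        if bounds_log is None:
            return x
        lo = np.array([b[0] for b in bounds_log])
        hi = np.array([b[1] for b in bounds_log])
        return np.clip(x, lo, hi)

    def penalized(x: np.ndarray) -> float:
        if bounds_log is not None:
            xc = clipped(x)
            if np.any(xc != x):
                return fun(xc) * (1.0 + float(np.sum((x - xc) ** 2)))
        return fun(x)

    rng = np.random.default_rng(seed)
    starts = [np.asarray(x0_log, dtype=float)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(x0_log + rng.uniform(-spread, spread, size=len(x0_log)))

    if fatol is None:
        fatol = max(1e-12, 1e-4 * abs(penalized(starts[0])))

    best = None
    for start in starts:
        res = minimize(
            penalized,
            clipped(start),
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": fatol,
                "maxiter": maxiter or 400 * len(x0_log),
                "adaptive": len(x0_log) > 3,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    info = {
        "success": bool(best.success),
        "message": str(best.message),
        "nfev": int(best.nfev),
        "nit": int(best.nit),
        "n_starts": len(starts),
    }
    return clipped(best.x), float(best.fun), info


def _hessian_log(fun, x_log: np.ndarray, f0: float, h: float = 5e-3) -> np.ndarray:
    """Central finite-difference Hessian in log10 space."""
    n = len(x_log)
    hess = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        fp[i] = fun(x_log + e)
        fm[i] = fun(x_log - e)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            fpp = fun(x_log + ei + ej)
            fmm = fun(x_log - ei - ej)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h**2)
    return hess


def fit(dataset: Dataset, spec: FitSpec) -> FitResult:
    """Minimize the objective over the free parameters of ``spec``.

    Deterministic for a given dataset, spec and seed.  Non-convergence is
    flagged in ``FitResult.convergence`` rather than raised.
    """
    names = spec.names
    n_obs = 6 * len(dataset)
    if n_obs < len(names):
        raise ValueError("fewer observations than free parameters")

    def fun(x_log: np.ndarray) -> float:
        values = {n: 10.0 ** v for n, v in zip(names, x_log)}
        return objective(
            _apply(spec, values), dataset,
            kind=spec.kind, protocol=spec.protocol,
            geometry=spec.geometry, sim_rtol=spec.sim_rtol,
            areas=spec.areas,
        )

    x0 = np.array([math.log10(spec.free[n]) for n in names])
    bounds_log = (
        [tuple(math.log10(b) for b in spec.bounds[n]) if n in spec.bounds
         else (x0[i] - 4.0, x0[i] + 4.0)
         for i, n in enumerate(names)]
    )
    x_best, f_best, info = minimize_log(
        fun, x0, bounds_log=bounds_log,
        n_starts=spec.n_starts, seed=spec.seed, spread=spec.start_spread,
    )

    estimates = {n: 10.0 ** v for n, v in zip(names, x_best)}

    # local curvature -> Wald-style intervals as a cheap default; use
    # profile_ci for the reported intervals of key parameters
    n_free = len(names)
    dof = max(n_obs - n_free, 1)
    s2 = max(f_best, 1e-300) / dof
    hess = _hessian_log(fun, x_best, f_best)
    try:
        cov = 2.0 * s2 * np.linalg.inv(hess)
        sd_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((n_free, n_free), np.nan)
        sd_log = np.full(n_free, np.nan)
    ci95 = {}
    for i, n in enumerate(names):
        if np.isfinite(sd_log[i]):
            half = 1.96 * sd_log[i]
            ci95[n] = (estimates[n] * 10.0 ** (-half), estimates[n] * 10.0 ** half)
        else:
            ci95[n] = (float("nan"), float("nan"))

    return FitResult(
        estimates=estimates,
        objective=f_best,
        ci95=ci95,
        covariance_proxy=cov,
        convergence=info,
        n_observations=n_obs,
    )


def profile_threshold(f_best: float, n_obs: int, n_free: int, level: float = 0.95) -> float:
    """Objective value at the profile-likelihood confidence boundary."""
    dof = max(n_obs - n_free, 1)
    fq = f_dist.ppf(level, 1, dof)
    return f_best * (1.0 + fq / dof)


def profile_interval(
    fun_profiled: Callable[[float], float],
    x_best_log: float,
    threshold: float,
    step: float = 0.05,
    max_steps: int = 80,
) -> tuple[float, float, bool, bool]:
    """Scan one log10 parameter outward until the objective crosses
    ``threshold``; returns (lo, hi, lo_open, hi_open) in natural units."""

    def walk(direction: int) -> tuple[float, bool]:
        prev_x, prev_f = x_best_log, fun_profiled(x_best_log)
        for k in range(1, max_steps + 1):
            x = x_best_log + direction * k * step
            fx = fun_profiled(x)
            if fx >= threshold:
                # linear interpolation of the crossing
                if fx == prev_f:
                    return 10.0 ** x, False
                frac = (threshold - prev_f) / (fx - prev_f)
                return 10.0 ** (prev_x + frac * (x - prev_x)), False
            prev_x, prev_f = x, fx
        return (0.0 if direction < 0 else math.inf), True

    lo, lo_open = walk(-1)
    hi, hi_open = walk(+1)
    return lo, hi, lo_open, hi_open


def profile_ci(
    dataset: Dataset,
    spec: FitSpec,
    result: FitResult,
    param_name: str,
    level: float = 0.95,
    step: float = 0.05,
    max_steps: int = 80,
) -> tuple[float, float, dict]:
    """Profile-likelihood confidence interval for one fitted parameter.

    The parameter is fixed on a log10 grid around its estimate while the
    remaining free parameters are re-optimized at each grid point.  Returns
    ``(lo, hi, info)``; an open bound is 0 / inf with a flag in ``info``.
    """
    if param_name not in result.estimates:
        raise KeyError(f"{param_name!r} was not a free parameter of this fit")
    names = spec.names
    others = [n for n in names if n != param_name]
    f_best = result.objective
    threshold = profile_threshold(f_best, result.n_observations, len(names), level)

    def fun_all(values: Mapping[str, float]) -> float:
        return objective(
            _apply(spec, values), dataset,
            kind=spec.kind, protocol=spec.protocol,
            geometry=spec.geometry, sim_rtol=spec.sim_rtol,
            areas=spec.areas,
        )

    x_others0 = np.array([math.log10(result.estimates[n]) for n in others])

    def fun_profiled(x_log: float) -> float:
        fixed = {param_name: 10.0 ** x_log}
        if not others:
            return fun_all(fixed)

        def inner(xo_log: np.ndarray) -> float:
            vals = dict(fixed)
            vals.update({n: 10.0 ** v for n, v in zip(others, xo_log)})
            return fun_all(vals)

        _, f_val, _ = minimize_log(inner, x_others0, xatol=2e-3)
        return f_val

    x_best_log = math.log10(result.estimates[param_name])
    lo, hi, lo_open, hi_open = profile_interval(
        fun_profiled, x_best_log, threshold, step=step, max_steps=max_steps
    )
    info = {
        "threshold": threshold,
        "lo_open": lo_open,
        "hi_open": hi_open,
        "level": level,
    }
    return lo, hi, info
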