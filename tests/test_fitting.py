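import math

import numpy as np
import pytest
from scipy import stats

from oligokin.fitting import (
    FitSpec,
    fit,
    minimize_log,
    objective,
    profile_interval,
    profile_threshold,
)
from oligokin.model import OligomerDistribution, simulate_condition
from oligokin.params import Condition, Protocol, RateParameters

# small condition set + short protocol keep these unit fits cheap
CONDS = [
    Condition(c_bulk=33e-9, dnp_fraction=0.05, t_incubation=120.0),
    Condition(c_bulk=6.6e-9, dnp_fraction=0.05, t_incubation=120.0),
    Condition(c_bulk=33e-9, dnp_fraction=0.0085, t_incubation=120.0),
]
PROTO = Protocol(t_wash=60.0, t_observe=600.0)


def make_dataset(params, conds=CONDS, rtol=1e-6):
    out = []
    for c in conds:
        sim = simulate_condition(params, c, protocol=PROTO, rtol=rtol)
        out.append((c, sim.distribution))
    return out


class TestObjective:
    def test_zero_on_self_generated_data(self, igg1):
        dataset = make_dataset(igg1)
        val = objective(igg1, dataset, protocol=PROTO, sim_rtol=1e-6)
        assert val == pytest.approx(0.0, abs=1e-16)

    def test_definition_matches_hand_formula(self, igg1):
        """Objective is the plain sum of squared fraction differences
        (observed vectors are normalized on entry)."""
        dataset = make_dataset(igg1)
        model_fractions = [dist.fractions for _, dist in dataset]
        observed = np.array([0.4, 0.3, 0.15, 0.1, 0.03, 0.02])
        perturbed = [(dataset[0][0], OligomerDistribution(observed))] + dataset[1:]
        val = objective(igg1, perturbed, protocol=PROTO, sim_rtol=1e-6)
        expected = float(np.sum((model_fractions[0] - observed) ** 2))
        assert val == pytest.approx(expected, rel=1e-9)

    def test_wrong_parameters_give_positive_objective(self, igg1):
        dataset = make_dataset(igg1)
        val = objective(
            igg1.updated(k1b=igg1.k1b / 2), dataset, protocol=PROTO, sim_rtol=1e-6
        )
        assert val > 1e-6

    def test_poisson_objective_needs_areas(self, igg1):
        dataset = make_dataset(igg1)
        with pytest.raises(ValueError):
            objective(igg1, dataset, kind="poisson")


class TestMinimizeLog:
    def test_quadratic_bowl(self):
        fun = lambda x: float((x[0] - 1.0) ** 2 + (x[1] + 2.0) ** 2)
        x, f, info = minimize_log(fun, np.array([0.0, 0.0]), fatol=1e-12)
        assert np.allclose(x, [1.0, -2.0], atol=1e-3)
        assert info["success"]

    def test_multistart_is_seeded(self):
        fun = lambda x: float(np.sum(x**2))
        a = minimize_log(fun, np.array([1.0]), n_starts=4, seed=5, fatol=1e-12)
        b = minimize_log(fun, np.array([1.0]), n_starts=4, seed=5, fatol=1e-12)
        assert a[0] == b[0] and a[1] == b[1]


class TestProfileInterval:
    def test_gaussian_case_matches_analytic(self):
        """For a quadratic objective the profile interval equals the
        analytic +/- 1.96 sigma interval (in log10 space)."""
        sigma = 0.1  # log10 units
        n_obs, n_free = 50, 1
        f_best = 1.0

        def fun(x_log):
            return f_best * (1.0 + ((x_log / sigma) ** 2) / (n_obs - n_free))

        threshold = profile_threshold(f_best, n_obs, n_free)
        lo, hi, lo_open, hi_open = profile_interval(
            fun, 0.0, threshold, step=0.01, max_steps=200
        )
        fq = stats.f.ppf(0.95, 1, n_obs - n_free)
        expected_half = sigma * math.sqrt(fq)  # ~1.96 sigma for large dof
        assert not lo_open and not hi_open
        assert math.log10(hi) == pytest.approx(expected_half, rel=0.02)
        assert math.log10(lo) == pytest.approx(-expected_half, rel=0.02)

    def test_flat_direction_reports_open_bound(self):
        fun = lambda x_log: 1.0  # totally uninformative
        lo, hi, lo_open, hi_open = profile_interval(fun, 0.0, 1.5, max_steps=10)
        assert lo_open and hi_open
        assert lo == 0.0 and hi == math.inf


class TestFit:
    def test_noiseless_single_parameter_recovery(self, igg1):
        dataset = make_dataset(igg1, rtol=1e-8)
        spec = FitSpec(
            free={"k1b": igg1.k1b * 3}, baseline=igg1,
            protocol=PROTO, sim_rtol=1e-7,
        )
        res = fit(dataset, spec)
        assert res.estimates["k1b"] == pytest.approx(igg1.k1b, rel=0.01)
        assert res.success

    def test_refit_from_optimum_is_idempotent(self, igg1):
        dataset = make_dataset(igg1, rtol=1e-8)
        spec = FitSpec(free={"k1b": igg1.k1b * 3}, baseline=igg1,
                       protocol=PROTO, sim_rtol=1e-7)
        first = fit(dataset, spec)
        spec2 = FitSpec(free={"k1b": first.estimates["k1b"]}, baseline=igg1,
                        protocol=PROTO, sim_rtol=1e-7)
        second = fit(dataset, spec2)
        assert second.estimates["k1b"] == pytest.approx(
            first.estimates["k1b"], rel=2e-3
        )
        assert second.objective <= first.objective * (1 + 1e-6) + 1e-12

    def test_grouping_contract_leaves_fixed_parameters_untouched(self, igg1):
        """A single-parameter refit of kT must not move any other rate."""
        modified_truth = igg1.updated(kT=0.093)
        dataset = make_dataset(modified_truth, rtol=1e-8)
        spec = FitSpec(free={"kT": 0.35}, baseline=igg1,
                       protocol=PROTO, sim_rtol=1e-7)
        res = fit(dataset, spec)
        refit = igg1.updated(kT=res.estimates["kT"])
        assert res.estimates["kT"] == pytest.approx(0.093, rel=0.02)
        assert refit.k1b == igg1.k1b and refit.k3 == igg1.k3
        assert refit.k2 == igg1.k2

    def test_profile_ci_brackets_estimate(self, igg1):
        from oligokin.fitting import profile_ci

        rng_noise = np.random.default_rng(0)
        dataset = []
        for cond, dist in make_dataset(igg1, rtol=1e-8):
            f = dist.fractions + rng_noise.normal(0, 0.01, 6)
            dataset.append((cond, OligomerDistribution(np.clip(f, 1e-6, None))))
        spec = FitSpec(free={"k1b": igg1.k1b * 2}, baseline=igg1,
                       protocol=PROTO, sim_rtol=1e-6)
        res = fit(dataset, spec)
        lo, hi, info = profile_ci(dataset, spec, res, "k1b", step=0.1,
                                  max_steps=25)
        assert lo < res.estimates["k1b"] < hi
        assert not info["lo_open"]

    def test_underdetermined_dataset_rejected(self, igg1):
        with pytest.raises(ValueError):
            fit([], FitSpec(free={"k1b": 1e-4}, baseline=igg1))
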