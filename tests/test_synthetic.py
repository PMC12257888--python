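import numpy as np
import pytest

from oligokin.biosensor import langmuir_simulate
from oligokin.forcespec import BellEvansParams, simulate_rupture_events
from oligokin.model import OligomerDistribution
from oligokin.params import IGG1_PARAMS, Condition, Protocol
from oligokin.synthetic import (
    FixtureSpec,
    default_conditions,
    figure4_conditions,
    generate_dataset,
    generate_fd_events,
    generate_gci_traces,
    sample_distribution_counts,
)

QUICK = dict(protocol=Protocol(t_wash=60.0, t_observe=120.0), sim_rtol=1e-6)


class TestConditionDesigns:
    def test_default_design_has_35_conditions(self):
        conds = default_conditions()
        assert len(conds) == 35
        assert {c.dnp_fraction for c in conds} == {0.0085, 0.025, 0.05}
        assert any(c.spa_conc > 0 for c in conds)
        assert any(c.mutant for c in conds)

    def test_figure4_grid(self):
        conds = figure4_conditions()
        assert len(conds) == 9
        assert all(c.t_incubation == 180.0 for c in conds)
        assert min(c.c_bulk for c in conds) == pytest.approx(6.6e-9)
        assert max(c.c_bulk for c in conds) == pytest.approx(33e-9)


class TestSampleCounts:
    def test_zero_particles(self):
        d = OligomerDistribution([0.5, 0.3, 0.1, 0.05, 0.03, 0.02])
        assert sample_distribution_counts(d, 0).tolist() == [0] * 6

    def test_seed_reproducibility(self):
        d = OligomerDistribution([0.5, 0.3, 0.1, 0.05, 0.03, 0.02])
        a = sample_distribution_counts(d, 300, seed=9)
        b = sample_distribution_counts(d, 300, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_multinomial_moments(self):
        fractions = np.array([0.5, 0.3, 0.1, 0.05, 0.03, 0.02])
        d = OligomerDistribution(fractions)
        n = 100_000
        counts = sample_distribution_counts(d, n, seed=1)
        sd = np.sqrt(n * fractions * (1 - fractions))
        assert np.all(np.abs(counts - n * fractions) < 4 * sd)
        assert counts.sum() == n


@pytest.fixture(scope="module")
def small_spec():
    return FixtureSpec(
        conditions=figure4_conditions()[:3], n_particles=200, seed=4, **QUICK
    )


class TestGenerateDataset:
    def test_schema_and_truth_record(self, small_spec):
        cond_df, count_df, truth = generate_dataset(IGG1_PARAMS, small_spec)
        assert list(cond_df.columns) == [
            "condition_id", "variant", "mutant", "c_bulk_nM",
            "dnp_fraction", "t_incubation_s", "spa_conc_uM",
        ]
        assert len(cond_df) == len(count_df) == 3
        assert count_df[[f"size_{s}" for s in range(1, 7)]].sum(axis=1).eq(200).all()
        assert truth["parameters"]["k1b"] == IGG1_PARAMS.k1b
        assert set(truth["fractions"]) == set(cond_df["condition_id"])

    def test_seeds_change_counts_not_truth(self, small_spec):
        import dataclasses

        other = dataclasses.replace(small_spec, seed=5)
        _, counts_a, truth_a = generate_dataset(IGG1_PARAMS, small_spec)
        _, counts_b, truth_b = generate_dataset(IGG1_PARAMS, other)
        assert truth_a["fractions"] == truth_b["fractions"]
        assert not counts_a.equals(counts_b)

    def test_noiseless_counts_match_rounded_expectation(self):
        spec = FixtureSpec(
            conditions=figure4_conditions()[:1], n_particles=500,
            noise="none", seed=0, **QUICK,
        )
        _, count_df, truth = generate_dataset(IGG1_PARAMS, spec)
        expected = np.rint(np.array(truth["fractions"]["c01"]) * 500)
        got = count_df.iloc[0][[f"size_{s}" for s in range(1, 7)]].to_numpy(float)
        np.testing.assert_array_equal(got, expected)

    def test_poisson_mode_records_area(self):
        spec = FixtureSpec(
            conditions=figure4_conditions()[:2], n_particles=300,
            noise="poisson", seed=3, **QUICK,
        )
        _, count_df, _ = generate_dataset(IGG1_PARAMS, spec)
        assert "area_um2" in count_df.columns
        assert (count_df["area_um2"] > 0).all()
        totals = count_df[[f"size_{s}" for s in range(1, 7)]].sum(axis=1)
        # Poisson totals fluctuate around the design size
        assert np.all(np.abs(totals - 300) < 5 * np.sqrt(300))


class TestDelegatedGenerators:
    def test_fd_events_delegate_to_rupture_sampler(self):
        df = generate_fd_events(
            BellEvansParams(1.5, 0.5), [1000.0, 5000.0], n_per_rate=50, seed=8
        )
        assert len(df) == 100
        assert set(df["loading_rate_pN_s"]) == {1000.0, 5000.0}
        rng = np.random.default_rng(8)
        expected = simulate_rupture_events(
            BellEvansParams(1.5, 0.5), 1000.0, 50, seed=int(rng.integers(2**31))
        )
        np.testing.assert_array_equal(
            df.loc[df["loading_rate_pN_s"] == 1000.0, "force_pN"].to_numpy(),
            expected,
        )

    def test_gci_zero_noise_equals_deterministic(self):
        traces = generate_gci_traces(3.1e4, 1.3e-1, 85.0, [1e-6], noise_sd=0.0)
        ref = langmuir_simulate(3.1e4, 1.3e-1, 85.0, 1e-6)
        np.testing.assert_array_equal(traces[0].response, ref.response)

    def test_gci_noise_is_seeded(self):
        a = generate_gci_traces(3.1e4, 1.3e-1, 85.0, [1e-6], noise_sd=1.0, seed=2)
        b = generate_gci_traces(3.1e4, 1.3e-1, 85.0, [1e-6], noise_sd=1.0, seed=2)
        np.testing.assert_array_equal(a[0].response, b[0].response)
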