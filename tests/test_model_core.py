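import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligokin.model import (
    IDX_EPI,
    IDX_SURF,
    N_STATES,
    check_reversibility_constraints,
    effective_rates,
    footprint_areas,
    implied_lower_branch_rates,
    ode_rhs,
    screening_weights,
    simulate_condition,
    states_to_distribution,
)
from oligokin.params import (
    SURFACE_COMPARTMENT_ALPHA,
    Condition,
    Protocol,
    ScreeningGeometry,
)

IGG_PER_STATE = np.array([1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6], dtype=float)


class TestScreeningWeights:
    def test_hexamer_weight_at_reference_density(self, geometry):
        # pi * (11.5 nm)^2 * 0.081 nm^-2
        w = screening_weights(geometry, 81e3)
        assert w[6] == pytest.approx(np.pi * 11.5**2 * 0.081, rel=1e-12)
        assert w[6] == pytest.approx(33.7, abs=0.1)

    def test_bivalent_monomer_weight(self, geometry):
        # gamma * d1 = 14.08 nm footprint diameter
        w = screening_weights(geometry, 81e3)
        assert w[1] == pytest.approx(np.pi * 7.04**2 * 0.081, rel=1e-12)
        assert w[1] == pytest.approx(12.6, abs=0.1)

    def test_zero_density_limit(self, geometry):
        assert np.all(screening_weights(geometry, 0.0) == 0.0)

    def test_footprints_monotone_monomer_to_hexamer(self, geometry):
        areas = footprint_areas(geometry)
        # bivalent monomer through hexamer footprints never shrink
        assert np.all(np.diff(areas[1:]) >= 0)
        assert areas[0] < areas[1]

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            screening_weights(ScreeningGeometry(d2=-1.0), 81e3)


class TestEffectiveRates:
    def test_wild_type_reference_surface_is_identity(self, igg1):
        r = effective_rates(igg1, Condition(dnp_fraction=0.05))
        assert (r.k1b, r.k3, r.k4) == (igg1.k1b, igg1.k3, igg1.k4)
        assert r.k2 == igg1.k2 and r.kT == igg1.kT

    def test_e430g_scales_captures_only(self, igg1):
        r = effective_rates(igg1, Condition(mutant=True, dnp_fraction=0.05))
        assert r.k3 == pytest.approx(2.5e-4 * 1.9)
        assert r.k4 == pytest.approx(6.5e-4 * 1.9)
        assert r.k1b == igg1.k1b  # ring closure unaffected by the mutation

    def test_sparse_surface_prefactor(self, igg1):
        r = effective_rates(igg1, Condition(dnp_fraction=0.0085))
        assert r.k1b == pytest.approx(3.2e-4 * 2.0)
        assert r.k1 == pytest.approx(1.7 * 3.1e4)
        assert r.k_minus1 == pytest.approx(1.3e-1)

    def test_unregistered_surface_raises(self, igg1):
        with pytest.raises(KeyError):
            effective_rates(igg1, Condition(dnp_fraction=0.012))


class TestOdeRhs:
    def test_initial_capture_only_term(self, igg1, geometry):
        cond = Condition(dnp_fraction=0.05)
        r = effective_rates(igg1, cond)
        w = screening_weights(geometry, cond.rho_epi)
        y = np.zeros(N_STATES)
        y[IDX_EPI] = 81e3
        y[IDX_SURF] = 1e-8
        dy = ode_rhs(y, r, w, c_bulk=1e-8)
        assert dy[0] == pytest.approx(1.02e4 * 1e-8 * 81e3)  # 8.262 um^-2 s^-1
        assert np.all(dy[1:12] == 0.0)

    def test_empty_system_is_stationary(self, igg1, geometry):
        cond = Condition(dnp_fraction=0.05)
        r = effective_rates(igg1, cond)
        w = screening_weights(geometry, cond.rho_epi)
        y = np.zeros(N_STATES)
        y[IDX_EPI] = cond.rho_epi
        assert np.all(ode_rhs(y, r, w, c_bulk=0.0) == 0.0)

    def test_negative_state_rejected(self, igg1, geometry):
        cond = Condition(dnp_fraction=0.05)
        r = effective_rates(igg1, cond)
        w = screening_weights(geometry, cond.rho_epi)
        y = np.zeros(N_STATES)
        y[0] = -1.0
        with pytest.raises(ValueError):
            ode_rhs(y, r, w, c_bulk=0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_transport_conservation_identity(self, data, igg1, geometry):
        """alpha * (total bound IgG)' + yIgG_surf' == kT (c_bulk - yIgG_surf)
        for every admissible state: IgG only enters or leaves the surface
        compartment through transport."""
        cond = Condition(dnp_fraction=0.05)
        r = effective_rates(igg1, cond)
        w = screening_weights(geometry, cond.rho_epi)
        y = np.zeros(N_STATES)
        for i in range(12):
            y[i] = data.draw(st.floats(0, 100), label=f"y{i}")
        y[IDX_SURF] = data.draw(st.floats(0, 1e-7), label="ysurf")
        y[IDX_EPI] = data.draw(st.floats(0, 8.1e4), label="yepi")
        c_bulk = data.draw(st.floats(0, 1e-7), label="c_bulk")
        phi = data.draw(st.floats(0, 1), label="phi")
        dy = ode_rhs(y, r, w, c_bulk, fc_free_fraction=phi)
        lhs = SURFACE_COMPARTMENT_ALPHA * float(IGG_PER_STATE @ dy[:12]) + dy[IDX_SURF]
        rhs = r.kT * (c_bulk - y[IDX_SURF])
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-20)


class TestStatesToDistribution:
    def test_single_monomer(self):
        y = np.zeros(N_STATES)
        y[0] = 1.0
        d = states_to_distribution(y)
        assert d.abundance.tolist() == [1, 0, 0, 0, 0, 0]
        assert d.total_igg_density == 1.0

    def test_dimer_pairing_and_total(self):
        y = np.zeros(N_STATES)
        y[2], y[3] = 2.0, 1.0  # y2b, y3b
        d = states_to_distribution(y)
        assert d.abundance[1] == 3.0
        assert d.total_igg_density == 6.0

    def test_hexamer_pairing(self):
        y = np.zeros(N_STATES)
        y[10], y[11] = 0.5, 0.5
        d = states_to_distribution(y)
        assert d.abundance[5] == 1.0
        assert d.total_igg_density == pytest.approx(6.0)

    def test_fractions_sum_to_one(self):
        y = np.zeros(N_STATES)
        y[:12] = np.linspace(1, 12, 12)
        assert states_to_distribution(y).fractions.sum() == pytest.approx(1.0)


class TestSimulateCondition:
    def test_no_fc_pathway_gives_pure_monomers(self, igg1, reference_condition,
                                               quick_protocol):
        res = simulate_condition(
            igg1.updated(k2=1e-30), reference_condition, protocol=quick_protocol
        )
        assert res.distribution.fractions[0] == pytest.approx(1.0)

    def test_langmuir_limit_closed_form(self, igg1):
        """With ring closure and Fc-Fc growth disabled the model reduces to
        1:1 epitope binding: occupancy c / (c + KD) at equilibrium."""
        kd = 2.1e-1 / 1.02e4
        p = igg1.updated(k1b=1e-30, k2=1e-30, kT=1e3)
        cond = Condition(c_bulk=kd, dnp_fraction=0.05, t_incubation=5e4)
        res = simulate_condition(
            p, cond, protocol=Protocol(t_wash=0.0, t_observe=0.0, averaging=False)
        )
        y1, yepi = res.final_state[0], res.final_state[IDX_EPI]
        assert y1 / (y1 + yepi) == pytest.approx(0.5, rel=1e-6)
        # detailed balance at equilibrium
        assert 1.02e4 * kd * yepi == pytest.approx(2.1e-1 * y1, rel=1e-6)

    def test_nonnegative_states_throughout(self, igg1, reference_condition):
        res = simulate_condition(igg1, reference_condition)
        scale = res.states.max()
        assert res.states.min() >= -1e-12 * scale

    def test_wash_semantics_option(self, igg1, reference_condition):
        held = simulate_condition(
            igg1, reference_condition, protocol=Protocol(t_observe=300.0)
        )
        zeroed = simulate_condition(
            igg1, reference_condition,
            protocol=Protocol(t_observe=300.0, wash_bulk="zero"),
        )
        # holding the bulk during the wash keeps loading the surface
        assert (
            held.distribution.total_igg_density
            > zeroed.distribution.total_igg_density
        )

    def test_free_screening_mode_runs_and_differs(self, igg1, reference_condition,
                                                  quick_protocol):
        total = simulate_condition(igg1, reference_condition, protocol=quick_protocol)
        free = simulate_condition(
            igg1, reference_condition, protocol=quick_protocol,
            geometry=ScreeningGeometry(screening="free"),
        )
        assert not np.allclose(
            total.distribution.abundance, free.distribution.abundance
        )

    def test_averaging_flag(self, igg1, reference_condition):
        proto_avg = Protocol(t_observe=600.0, averaging=True)
        proto_end = Protocol(t_observe=600.0, averaging=False)
        avg = simulate_condition(igg1, reference_condition, protocol=proto_avg)
        end = simulate_condition(igg1, reference_condition, protocol=proto_end)
        # bound material decays after the wash, so the time average exceeds
        # the endpoint density
        assert avg.distribution.total_igg_density > end.distribution.total_igg_density


class TestReversibilityConstraints:
    BASE = {
        "k1b": 3.2e-4, "k3": 2.5e-4, "k3_star": 2.5e-4,
        "k4": 6.5e-4, "k4_star": 6.5e-4,
    }

    def test_consistent_rates_give_zero_residuals(self):
        params = dict(self.BASE)
        params.update({f"k1b_{i}": 3.2e-4 for i in range(2, 6)})
        params.update({"k5": 2.0, "k6": 1.0, "k7": 6.5e-4 / 2.0})
        res = check_reversibility_constraints(params)
        assert np.allclose(res, 0.0, atol=1e-12)

    def test_implied_lower_branch_rates(self):
        params = {"k1b": 3.2e-4, "k3": 2.0, "k3_star": 1.0, "k4": 3.0, "k4_star": 1.0}
        implied = implied_lower_branch_rates(params)
        assert implied["k1b_4"] == pytest.approx(3.2e-4 * 2 * 9)
        assert implied["k1b_2"] == pytest.approx(3.2e-4 * 2)

    def test_violation_shows_as_log_residual(self):
        params = dict(self.BASE)
        params.update({f"k1b_{i}": 3.2e-4 for i in range(2, 6)})
        # violate the hexamer-closure constraint by a factor of two
        params.update({"k5": 2.0, "k6": 1.0, "k7": 6.5e-4})
        res = check_reversibility_constraints(params)
        assert res[-1] == pytest.approx(np.log(2.0))

    def test_nonpositive_rate_rejected(self):
        params = dict(self.BASE)
        params["k1b_2"] = 0.0
        with pytest.raises(ValueError):
            check_reversibility_constraints(params)
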