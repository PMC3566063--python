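"""Hodgkin-Huxley current definitions, gate updates, calcium handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from obtriad.channels import (
    CalciumPool,
    CatalogError,
    GatingRule,
    calcium_update,
    catalog_kinds,
    channel_current,
    make_channel,
    nernst_ca,
    update_gate,
)


@pytest.fixture(scope="module")
def na_channel():
    return make_channel("pg_na", 1e-3)


class TestChannelCurrent:
    def test_zero_driving_force(self, na_channel):
        assert channel_current(na_channel, 50.0, (0.4, 0.7), 50.0) == 0.0

    def test_zero_gbar(self):
        spec = make_channel("pg_na", 0.0)
        assert channel_current(spec, -20.0, (0.9, 0.5), 50.0) == 0.0

    def test_hand_value_single_squared_gate(self):
        # gbar 1e-3 S/cm^2, one gate 0.5 with power 2, driving force 10 mV
        rule = GatingRule(steady_state=lambda v: np.full_like(v, 0.5),
                          time_constant=lambda v: np.full_like(v, 1.0),
                          power=2)
        from obtriad.channels import ChannelSpec

        spec = ChannelSpec(name="toy", gates=(rule,), gbar=1e-3, reversal=0.0)
        i = channel_current(spec, 10.0, (0.5,), 0.0)
        assert i == pytest.approx(1e-3 * 0.25 * 10.0)  # 2.5e-3 mA/cm^2


class TestGateUpdate:
    def test_steady_state_is_fixed_point(self, na_channel):
        rule = na_channel.gates[0]
        g0 = float(rule.steady_state(np.array(-50.0)))
        assert update_gate(rule, g0, -50.0, 0.05) == pytest.approx(g0, abs=1e-12)

    def test_long_step_relaxes_to_steady_state(self, na_channel):
        rule = na_channel.gates[1]
        inf = float(rule.steady_state(np.array(-30.0)))
        out = update_gate(rule, 0.9, -30.0, 1e4)
        assert out == pytest.approx(inf, abs=1e-6)

    def test_exact_exponential_matches_analytic_relaxation(self, na_channel):
        rule = na_channel.gates[0]
        v, g0, dt = -45.0, 0.2, 0.7
        inf = float(rule.steady_state(np.array(v)))
        tau = float(rule.time_constant(np.array(v)))
        expected = inf + (g0 - inf) * np.exp(-dt / tau)
        assert update_gate(rule, g0, v, dt) == pytest.approx(expected, rel=1e-12)

    def test_instantaneous_rule_jumps_to_steady_state(self):
        rule = GatingRule(
            steady_state=lambda v: 1.0 / (1.0 + np.exp(-(v + 40.0) / 5.0)),
            time_constant="instantaneous",
        )
        assert update_gate(rule, 0.0, -40.0, 1e-6) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=60)
    @given(g=st.floats(0.0, 1.0), v=st.floats(-120.0, 60.0),
           dt=st.floats(1e-3, 10.0))
    def test_gate_stays_in_unit_interval(self, g, v, dt):
        rule = make_channel("pg_cat", 1e-3).gates[0]
        out = update_gate(rule, g, v, dt)
        assert 0.0 <= out <= 1.0


class TestCalcium:
    def test_resting_equilibrium(self):
        pool = CalciumPool()
        ca = calcium_update(pool, 0.0, pool.resting_mM, 0.05)
        assert ca == pytest.approx(pool.resting_mM, rel=1e-12)

    def test_decay_toward_rest_matches_first_order_kinetics(self):
        pool = CalciumPool(removal_tau_ms=5.0)
        ca0, dt = 1e-3, 0.01
        ca = ca0
        for _ in range(500):  # 5 ms
            ca = calcium_update(pool, 0.0, ca, dt)
        analytic = pool.resting_mM + (ca0 - pool.resting_mM) * np.exp(-1.0)
        assert ca == pytest.approx(analytic, rel=1e-3)

    def test_sustained_influx_raises_concentration_monotonically(self):
        pool = CalciumPool()
        ca, history = pool.resting_mM, []
        for _ in range(200):
            ca = calcium_update(pool, -0.05, ca, 0.05)  # inward current
            history.append(float(ca))
        assert all(b >= a for a, b in zip(history, history[1:]))
        assert history[-1] > pool.resting_mM

    def test_floor_is_enforced(self):
        pool = CalciumPool(floor_mM=1e-8)
        ca = calcium_update(pool, 1.0, 2e-8, 50.0)  # strong outward current
        assert ca >= 1e-8


class TestNernst:
    def test_symmetric_concentrations_give_zero(self):
        assert nernst_ca(1.0, 1.0) == 0.0

    def test_e_squared_ratio_gives_rt_over_f(self):
        # (RT/2F) ln(e^2) = RT/F ~ 25.26 mV at 293.15 K
        e = nernst_ca(1.0, np.e**2, temperature_K=293.15)
        assert e == pytest.approx(25.262, abs=0.005)

    def test_physiological_gradient(self):
        # 2 mM outside vs 1e-4 mM inside at 308.15 K
        e = nernst_ca(1e-4, 2.0, temperature_K=308.15)
        assert e == pytest.approx(131.49, abs=0.05)

    def test_rejects_nonpositive_concentrations(self):
        with pytest.raises(ValueError):
            nernst_ca(0.0, 2.0)


class TestCatalog:
    def test_unknown_kind_raises(self):
        with pytest.raises(CatalogError):
            make_channel("not_a_channel", 1e-3)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            make_channel("pg_na", -1.0)

    def test_repeated_calls_return_identical_spec(self):
        assert make_channel("pg_kdr", 0.02) is make_channel("pg_kdr", 0.02)

    def test_all_cell_channel_kinds_present(self):
        kinds = set(catalog_kinds())
        assert {"pg_na", "pg_kdr", "pg_ka", "pg_h", "pg_cat",
                "mit_na", "mit_kfast", "mit_ks", "mit_ka", "mit_kca", "mit_lca",
                "grc_na", "grc_kdr", "grc_ka", "grc_km"} <= kinds

    def test_calcium_channel_uses_nernst_reversal(self):
        cat = make_channel("pg_cat", 1e-3)
        assert cat.uses_nernst and cat.feeds_calcium


class TestVoltageClampSteadyState:
    @pytest.mark.parametrize("kind,gbar", [("pg_na", 0.01), ("mit_kfast", 0.02)])
    def test_clamped_gates_converge_to_steady_state_product(self, kind, gbar):
        """Under a long voltage clamp, the simulated conductance equals
        gbar * prod(g_inf(V)^p)."""
        from obtriad.cable import (CellModel, CompartmentGeometry, CurrentPulse,
                                   Network, PassiveParameters, SolverConfig)
        from obtriad.synapses import GradedSynapse

        v_clamp = -35.0
        spec = make_channel(kind, gbar)
        cell = CellModel(
            name="clamp",
            compartments=(CompartmentGeometry("soma", 20.0, 20.0),),
            passive=PassiveParameters(resting_potential=v_clamp,
                                      leak_reversal=v_clamp),
            channels=(("soma", spec),),
        )
        # enormous graded conductance with reversal at the clamp potential
        clamp = GradedSynapse(pre=("clamp", "soma"), post=("clamp", "soma"),
                              gmax=1e4, reversal=v_clamp, threshold=-1e3,
                              slope=1.0)
        net = Network(cell, [clamp])
        state = net.init_state(v0=v_clamp)
        net.run(SolverConfig(dt=0.05, t_stop=500.0), [], state=state)
        open_sim = 1.0
        for gi, rule in enumerate(spec.gates):
            open_sim *= state.gates[gi] ** rule.power
        open_inf = 1.0
        for rule in spec.gates:
            open_inf *= float(rule.steady_state(np.array(v_clamp))) ** rule.power
        assert open_sim == pytest.approx(open_inf, rel=1e-3)
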