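"""Cable discretization and implicit-solver correctness."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from obtriad.cable import (
    CellModel,
    CompartmentGeometry,
    CurrentPulse,
    Network,
    NumericalBlowupError,
    PassiveParameters,
    SolverConfig,
    StructuralError,
    VoltageTrace,
    axial_coupling,
)
from obtriad.channels import make_channel


def _two_comp_cell(length=100.0, diameter=1.0, ra=100.0):
    return CellModel(
        name="c",
        compartments=(
            CompartmentGeometry("a", length, diameter),
            CompartmentGeometry("b", length, diameter, parent="a"),
        ),
        passive=PassiveParameters(axial_resistivity=ra),
    )


class TestAxialCoupling:
    def test_two_identical_cylinders_hand_value(self):
        # g = 1 / (2 * R_a * (L/2) / (pi r^2)) for L=100um, d=1um, Ra=100 Ohm cm
        cell = _two_comp_cell()
        table = axial_coupling(cell)
        r_half_ohm = 100.0 * (50e-4) / (math.pi * (0.5e-4) ** 2)
        expected_uS = 1.0 / (2 * r_half_ohm) * 1e6
        assert table[("a", "b")] == pytest.approx(expected_uS, rel=1e-12)
        assert table[("b", "a")] == table[("a", "b")]
        assert table[("a", "b")] == pytest.approx(7.853981634e-3, rel=1e-6)

    def test_single_compartment_empty_table(self):
        cell = CellModel(
            name="c",
            compartments=(CompartmentGeometry("soma", 10.0, 10.0),),
            passive=PassiveParameters(),
        )
        assert axial_coupling(cell) == {}

    def test_diameter_scaling_quadruples_conductance(self):
        g1 = axial_coupling(_two_comp_cell(diameter=1.0))[("a", "b")]
        g2 = axial_coupling(_two_comp_cell(diameter=2.0))[("a", "b")]
        assert g2 == pytest.approx(4.0 * g1, rel=1e-12)


class TestStructure:
    def test_two_roots_rejected(self):
        with pytest.raises(StructuralError):
            CellModel(
                name="bad",
                compartments=(
                    CompartmentGeometry("a", 10, 1),
                    CompartmentGeometry("b", 10, 1),
                ),
                passive=PassiveParameters(),
            )

    def test_unknown_parent_rejected(self):
        with pytest.raises(StructuralError):
            CellModel(
                name="bad",
                compartments=(
                    CompartmentGeometry("a", 10, 1),
                    CompartmentGeometry("b", 10, 1, parent="zzz"),
                ),
                passive=PassiveParameters(),
            )


class TestPassiveSolver:
    def test_rc_step_response_closed_form(self, passive_cell):
        # V(t) = V_rest + I R (1 - exp(-t/RC)) for a step current
        area = passive_cell.compartments[0].area_cm2
        g = passive_cell.passive.leak_conductance_density * area * 1e6  # uS
        c = passive_cell.passive.specific_capacitance * area * 1e3  # nF
        amp = 0.05  # nA
        cfg = SolverConfig(dt=0.05, t_stop=200.0)
        trace = Network(passive_cell).run(
            cfg, [CurrentPulse((None, "soma"), amp, 0.0, 200.0)])
        t = trace.times[1:]
        analytic = -65.0 + amp / g * (1.0 - np.exp(-t * g / c))
        err = np.max(np.abs(trace["soma"][1:] - analytic))
        assert err < 0.01 * (amp / g)  # within 1% of the step amplitude

    def test_input_resistance_matches_parallel_leak(self, passive_cell):
        area = passive_cell.compartments[0].area_cm2
        r_analytic = 1.0 / (passive_cell.passive.leak_conductance_density * area * 1e6)
        cfg = SolverConfig(dt=0.05, t_stop=400.0)
        trace = Network(passive_cell).run(
            cfg, [CurrentPulse((None, "soma"), -0.01, 50.0, 350.0)])
        dv = trace["soma"][-1] - (-65.0)
        r_measured = dv / (-0.01)
        assert r_measured == pytest.approx(r_analytic, rel=0.01)

    def test_rest_is_a_fixed_point(self, passive_cell):
        cfg = SolverConfig(dt=0.05, t_stop=100.0)
        trace = Network(passive_cell).run(cfg, [])
        assert np.max(np.abs(trace["soma"] - (-65.0))) < 1e-9


def _hh_single_compartment():
    """One compartment with Traub-type Na and delayed-rectifier channels."""
    na = make_channel("pg_na", 0.05)
    kdr = make_channel("pg_kdr", 0.015)
    return CellModel(
        name="hh",
        compartments=(CompartmentGeometry("soma", 30.0, 30.0),),
        passive=PassiveParameters(
            leak_conductance_density=1e-4,
            leak_reversal=-65.0,
            resting_potential=-65.0,
        ),
        channels=(("soma", na), ("soma", kdr)),
    )


def _hh_oracle(cell, amp, t_stop, onset=5.0):
    """High-accuracy adaptive integration of the same single-compartment
    Hodgkin-Huxley equations (independent of the fixed-step solver)."""
    comp = cell.compartments[0]
    area = comp.area_cm2
    gleak = cell.passive.leak_conductance_density * area * 1e6
    cap = cell.passive.specific_capacitance * area * 1e3
    channels = [(spec, spec.gbar * area * 1e6) for _, spec in cell.channels]
    gates = [(spec, rule) for spec, _ in channels for rule in spec.gates]

    def rhs(t, y):
        v = y[0]
        out = [0.0]
        i_ion = gleak * (v - cell.passive.leak_reversal)
        gi = 1
        for spec, g_uS in channels:
            o = 1.0
            for rule in spec.gates:
                o *= y[gi] ** rule.power
                gi += 1
            i_ion += g_uS * o * (v - spec.reversal)
        drive = amp if t > onset else 0.0
        out[0] = (drive - i_ion) / cap
        gi = 1
        for spec, _ in channels:
            for rule in spec.gates:
                inf = float(rule.steady_state(np.array(v)))
                tau = float(rule.time_constant(np.array(v)))
                out.append((inf - y[gi]) / tau)
                gi += 1
        return out

    y0 = [cell.passive.resting_potential]
    for spec, _ in channels:
        for rule in spec.gates:
            y0.append(float(rule.steady_state(np.array(y0[0]))))
    sol = solve_ivp(rhs, (0.0, t_stop), y0, rtol=1e-10, atol=1e-10,
                    dense_output=True, max_step=0.5)
    return sol


class TestConvergence:
    def test_backward_euler_first_order_on_subthreshold_response(self):
        """Halving dt halves the maximum deviation from a high-accuracy
        adaptive-ODE oracle (tolerance 1e-10) on a subthreshold response
        with active sodium/potassium currents."""
        cell = _hh_single_compartment()
        amp, t_stop = 0.02, 60.0
        oracle = _hh_oracle(cell, amp, t_stop)
        errors = []
        for dt in (0.1, 0.05, 0.025, 0.0125):
            cfg = SolverConfig(dt=dt, t_stop=t_stop)
            trace = Network(cell).run(
                cfg, [CurrentPulse((None, "soma"), amp, 5.0, t_stop - 5.0)])
            v_ref = oracle.sol(trace.times)[0]
            errors.append(np.max(np.abs(trace["soma"] - v_ref)))
        errors = np.array(errors)
        ratios = errors[:-1] / errors[1:]
        assert np.all(ratios > 1.7)
        assert np.all(ratios < 2.3)

    def test_spike_time_converges_to_oracle(self):
        """For a spiking response the action-potential peak time converges
        to the adaptive-oracle peak time as dt shrinks (first order on
        average)."""
        cell = _hh_single_compartment()
        amp, t_stop = 0.25, 60.0
        oracle = _hh_oracle(cell, amp, t_stop)
        tt = np.linspace(0.0, t_stop, 600001)
        t_peak_oracle = tt[np.argmax(oracle.sol(tt)[0])]
        errors = []
        for dt in (0.1, 0.05, 0.025, 0.0125):
            cfg = SolverConfig(dt=dt, t_stop=t_stop)
            trace = Network(cell).run(
                cfg, [CurrentPulse((None, "soma"), amp, 5.0, t_stop - 5.0)])
            t_peak = trace.times[np.argmax(trace["soma"])]
            errors.append(abs(t_peak - t_peak_oracle))
        assert all(b < a for a, b in zip(errors, errors[1:]))
        assert errors[0] / errors[-1] >= 4.0  # ~8x dt refinement


class TestRunContract:
    def test_repeated_runs_bitwise_identical(self, pg_cell):
        from obtriad.cells import pg_autapse

        syn = [pg_autapse(pg_cell)]
        cfg = SolverConfig(dt=0.05, t_stop=300.0)
        stim = [CurrentPulse((None, "soma"), 0.1, 100.0, 150.0)]
        a = Network(pg_cell, syn).run(cfg, stim)
        b = Network(pg_cell, syn).run(cfg, stim)
        for lab in a.labels:
            assert np.array_equal(a[lab], b[lab])

    def test_voltage_bounded_under_standard_protocol(self, pg_cell):
        from obtriad.cells import pg_autapse

        cfg = SolverConfig(dt=0.05, t_stop=1000.0)
        trace = Network(pg_cell, [pg_autapse(pg_cell)]).run(
            cfg, [CurrentPulse((None, "soma"), 0.1, 200.0, 600.0)])
        for lab in trace.labels:
            assert trace[lab].min() >= -120.0
            assert trace[lab].max() <= 60.0

    def test_blowup_reports_compartment_and_time(self, passive_cell):
        cfg = SolverConfig(dt=0.05, t_stop=10.0)
        with pytest.raises(NumericalBlowupError, match="soma"):
            Network(passive_cell).run(
                cfg, [CurrentPulse((None, "soma"), 1e6, 0.0, 10.0)])

    def test_stimulus_past_t_stop_warns(self, passive_cell):
        cfg = SolverConfig(dt=0.05, t_stop=10.0)
        with pytest.warns(UserWarning, match="truncated"):
            Network(passive_cell).run(
                cfg, [CurrentPulse((None, "soma"), 0.01, 5.0, 100.0)])

    def test_trace_csv_round_trip(self, passive_cell, tmp_path):
        cfg = SolverConfig(dt=0.05, t_stop=20.0)
        trace = Network(passive_cell).run(
            cfg, [CurrentPulse((None, "soma"), 0.02, 2.0, 10.0)])
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = VoltageTrace.from_csv(path)
        assert np.allclose(back.times, trace.times)
        assert np.allclose(back["soma"], trace["soma"])
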