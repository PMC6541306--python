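"""Rate dynamics and Heun integration: hand-checked input compositions,
fixed points, integrator accuracy and rectification invariants."""

import numpy as np
import pytest
from dataclasses import replace

from somvip.circuit import (
    CircuitSpec,
    ConnectivityParams,
    PCParams,
    STFParams,
    build_circuit,
)
from somvip.dynamics import (
    DEFAULT_DT,
    Simulator,
    adaptation_rhs,
    pc_inputs,
    pc_rate_rhs,
    simulate,
    stf_rhs,
)
from somvip.protocols import Sinusoid, StimulusProtocol
from somvip import meanfield

from conftest import build_quiet, motif_spec

PC = PCParams()


class TestPCInputs:
    def test_background_only_composition(self):
        """x_E=17.5, x_D=21, all rates zero: dendritic test current 20.755/s
        stays below the calcium threshold and the total drive is 17.745/s."""
        inp = pc_inputs(np.zeros(1), None, None, 17.5, 21.0, None, None, None, PC)
        assert inp.i_d0 == pytest.approx(0.31 * 17.5 + 0.73 * 21.0)
        assert inp.i_d0 < PC.theta_c
        assert np.all(inp.c == 0)
        assert inp.i_total == pytest.approx(0.27 * 21.0 + 0.69 * 17.5)

    def test_all_zero(self):
        inp = pc_inputs(np.zeros(2), None, None, 0.0, 0.0, None, None, None, PC)
        for f in (inp.i_syn_e, inp.i_syn_d, inp.i_d0, inp.c, inp.i_total):
            assert np.all(np.asarray(f) == 0)

    def test_heaviside_strict_at_threshold(self):
        """The calcium event requires i_d0 strictly above theta_c
        (H(0) = 0 convention)."""
        # exactly representable arrangement: i_d0 = 0.5 * 28 = 14 = theta_c
        pc = PCParams(lambda_d=0.5, theta_c=14.0)
        inp = pc_inputs(np.zeros(1), None, None, 0.0, 28.0, None, None, None, pc)
        assert inp.i_d0 == pc.theta_c
        assert np.all(inp.c == 0)
        inp2 = pc_inputs(np.zeros(1), None, None, 0.0, 28.5, None, None, None, pc)
        assert np.all(inp2.c == pc.c_amp)

    def test_calcium_event_boosts_total_drive(self):
        x_d = 45.0  # i_d0 = 32.85 > 28
        inp = pc_inputs(np.zeros(1), None, None, 0.0, x_d, None, None, None, PC)
        assert np.all(inp.c == PC.c_amp)
        assert inp.i_total == pytest.approx(PC.lambda_d * (x_d + PC.c_amp))


class TestScalarRHS:
    def test_pc_fixed_point(self):
        """With total drive 17.745/s and rheobase 14/s the somatic rate
        settles at 3.745/s."""
        inp = pc_inputs(np.zeros(1), None, None, 17.5, 21.0, None, None, None, PC)
        r_star = np.maximum(inp.i_total - PC.theta, 0.0)
        assert r_star == pytest.approx(3.745)
        assert pc_rate_rhs(r_star, inp, PC) == pytest.approx(0.0)

    def test_subthreshold_drive_relaxes_to_zero(self):
        inp = pc_inputs(np.zeros(1), None, None, 10.0, 0.0, None, None, None, PC)
        assert pc_rate_rhs(np.array([2.0]), inp, PC) < 0

    @pytest.mark.parametrize("b, r, a_ss", [(0.5, 4.0, 2.0), (0.0, 7.0, 0.0)])
    def test_adaptation_steady_state(self, b, r, a_ss):
        assert adaptation_rhs(a_ss, r, b, 0.1) == pytest.approx(0.0)
        assert adaptation_rhs(a_ss + 1.0, r, b, 0.1) < 0

    def test_stf_rhs_fixed_points(self):
        stf = STFParams(u_s=0.4, tau_f=0.2)
        assert stf_rhs(0.4, 0.0, stf) == pytest.approx(0.0)
        assert stf_rhs(1.0, 50.0, stf) <= 0
        # steady state at rate r equals the closed form
        from somvip.circuit import stf_steady_state
        u_star = stf_steady_state(0.4, 0.2, 3.0)
        assert stf_rhs(u_star, 3.0, stf) == pytest.approx(0.0, abs=1e-12)


def _uncoupled_circuit(x=5.0):
    """SOM/VIP units with all synaptic totals zero and background x."""
    spec = motif_spec(0.0, background={"S": x, "V": x})
    return build_circuit(spec, seed=0)


class TestIntegrator:
    def test_zero_derivative_state_unchanged(self):
        c = _uncoupled_circuit(5.0)
        sim = Simulator(c)
        st = sim.initial_state()
        st.r_s[:] = 5.0
        st.r_v[:] = 5.0
        res = sim.run(_const(sim), 0.01, initial=st)
        assert np.allclose(res.final_state.r_s, 5.0, atol=1e-12)

    def test_heun_matches_closed_form_on_linear_ode(self):
        """For tau r' = x - r the Heun map is
        r <- r (1 - h + h^2/2) + x (h - h^2/2), h = dt/tau."""
        c = _uncoupled_circuit(5.0)
        tau = c.spec.interneuron_tau
        dt = DEFAULT_DT
        res = simulate(c, duration=10 * dt, dt=dt, store_stride=dt)
        h = dt / tau
        r = 0.0
        for _ in range(10):
            r = r * (1 - h + 0.5 * h * h) + 5.0 * (h - 0.5 * h * h)
        assert res.final_state.r_s[0] == pytest.approx(r, abs=1e-14)

    def test_step_halving_convergence_second_order(self):
        """On a smooth, rectification-free protocol the global error decays
        ~ dt^2: halving dt shrinks it by about four."""
        spec = motif_spec(0.5, b=0.3, tau_a=0.05)
        c = build_circuit(spec, seed=0)
        proto = StimulusProtocol(c.background)
        proto.add("V", Sinusoid(period=0.05, amplitude=0.5))

        def final(dt):
            return simulate(c, proto, duration=0.2, dt=dt,
                            store_stride=0.2).final_state.r_s

        ref = final(DEFAULT_DT / 8)
        e1 = np.abs(final(DEFAULT_DT) - ref).max()
        e2 = np.abs(final(DEFAULT_DT / 2) - ref).max()
        assert e1 / e2 > 3.0  # order >= 2

    def test_dt_above_maximum_rejected(self):
        c = _uncoupled_circuit()
        with pytest.raises(ValueError):
            simulate(c, duration=0.1, dt=1e-4)

    def test_free_units_relax_exponentially(self):
        """With all weights zero each unit relaxes exactly exponentially to
        its background (up to integrator accuracy)."""
        c = _uncoupled_circuit(5.0)
        res = simulate(c, duration=0.1, store_stride=1e-3)
        tau = c.spec.interneuron_tau
        expected = 5.0 * (1 - np.exp(-res.t / tau))
        assert np.allclose(res.population_mean("S"), expected, atol=1e-6)

    def test_nonfinite_state_aborts(self):
        c = _uncoupled_circuit(5.0)
        sim = Simulator(c)

        class Bomb:
            def drives(self, t, t_step, classes):
                return {cl: np.nan for cl in classes}

        with pytest.raises(FloatingPointError):
            sim.run(Bomb(), 0.01)


def _const(sim):
    class P:
        def drives(self, t, t_step, classes):
            return {c: sim.baseline[c] for c in classes}
    return P()


class TestResultExport:
    def test_tidy_frame_and_summary(self):
        c = _uncoupled_circuit(5.0)
        res = simulate(c, duration=0.02, store_stride=1e-2)
        df = res.to_frame()
        assert set(df.columns) == {"time", "population", "unit", "variable", "value"}
        assert set(df["population"]) == {"S", "V"}
        n_units = c.n("S") + c.n("V")
        # rate, adaptation and facilitation variables at 3 stored samples
        assert len(df) == 3 * 3 * n_units
        summary = res.summary()
        assert summary["r_s_final_mean"] == pytest.approx(
            res.final_state.r_s.mean())


class TestLinearRegimeEquivalence:
    def test_steady_state_matches_meanfield(self):
        """No rectification active, b=0, u=1: the simulated interneuron
        steady state equals the closed-form solution to 1e-6/s."""
        spec = CircuitSpec(
            variant="interneuron_only",
            connectivity=ConnectivityParams().with_mutual_inhibition(0.6, 0.5),
        )
        c = build_circuit(spec, seed=4)
        res = simulate(c, duration=1.5)
        p = meanfield.params_from_circuit(c)
        r_pv, r_som, r_vip = meanfield.meanfield_steady_state(p)
        assert res.final_state.r_p.mean() == pytest.approx(r_pv, abs=1e-6)
        assert res.final_state.r_s.mean() == pytest.approx(r_som, abs=1e-6)
        assert res.final_state.r_v.mean() == pytest.approx(r_vip, abs=1e-6)


class TestNonNegativity:
    @pytest.mark.parametrize("w, b", [(0.7, 0.2), (1.4, 1.0), (1.8, 0.1)])
    def test_rates_and_u_bounds_hold(self, w, b):
        spec = replace(motif_spec(w, b), stf=STFParams(u_s=0.3, tau_f=0.1))
        c = build_quiet(spec, seed=5)
        sim = Simulator(c)
        st = sim.initial_state()
        st.r_v += 1.0
        res = sim.run(_const(sim), 1.0, initial=st)
        for key in ("r_s", "r_v"):
            assert np.all(res.data[key] >= 0)
        for key in ("u_s", "u_v"):
            assert np.all((res.data[key] >= 0) & (res.data[key] <= 1))
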