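"""Mean-field theory: closed-form steady states and slopes, amplification
index, linearized block systems, regime boundaries and the theoretical
oscillation frequency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somvip.meanfield import (
    MeanFieldParams,
    amplification_index_analytic,
    build_linearized_system,
    classify_regime_theory,
    meanfield_steady_state,
    oscillation_frequency_theory,
    slope_full,
    slope_ref,
    transfer_amplitude_theory,
    wta_onset_bisection,
)


class TestSteadyState:
    def test_symmetric_calibrated_point(self):
        p = MeanFieldParams(w_sv=0.7, w_vs=0.7, x_som=5.1, x_vip=5.1, x_pv=11.4)
        r_pv, r_som, r_vip = meanfield_steady_state(p)
        assert r_som == pytest.approx(3.0)
        assert r_vip == pytest.approx(3.0)
        assert r_pv == pytest.approx(3.0)

    def test_uncoupled_rates_equal_inputs(self):
        p = MeanFieldParams(w_sv=0, w_vs=0, w_ps=0, w_pp=0,
                            x_pv=2.0, x_som=4.0, x_vip=6.0)
        assert meanfield_steady_state(p) == pytest.approx((2.0, 4.0, 6.0))

    def test_modulation_suppresses_som(self):
        p = MeanFieldParams(w_sv=0.7, w_vs=0.7, x_som=5.1, x_vip=5.1)
        _, r0, _ = meanfield_steady_state(p)
        _, r1, _ = meanfield_steady_state(
            MeanFieldParams(w_sv=0.7, w_vs=0.7, x_som=5.1, x_vip=5.1, x_mod=0.5))
        assert r1 < r0

    def test_singular_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            meanfield_steady_state(MeanFieldParams(w_sv=1.0, w_vs=1.0))


class TestSlopes:
    def test_reference_limit_unity(self):
        p = MeanFieldParams(w_ps=0.0, w_ss=0.0)
        assert slope_ref(p) == pytest.approx(1.0)

    def test_full_equals_reference_without_feedback(self):
        # w_sv=1, w_vs=0: one-way inhibition, slopes coincide
        p = MeanFieldParams(w_sv=1.0, w_vs=0.0, w_ps=0.0, w_pp=0.0)
        assert slope_full(p) == pytest.approx(slope_ref(p))

    def test_hand_value(self):
        p = MeanFieldParams(w_sv=0.9, w_vs=0.9, w_ps=1.3, w_pp=1.5)
        assert slope_full(p) == pytest.approx((1 + 1.3 / 2.5) * 0.9 / 0.19, rel=1e-12)


class TestAmplificationIndex:
    def test_one_way_inhibition_gives_zero(self):
        p = MeanFieldParams(w_sv=1.0, w_vs=0.0)
        assert amplification_index_analytic(p) == pytest.approx(0.0)

    def test_hand_value(self):
        p = MeanFieldParams(w_sv=0.9, w_vs=0.9)
        assert amplification_index_analytic(p) == pytest.approx(
            math.log2(0.9 / 0.19), rel=1e-12)

    def test_sentinel_beyond_wta(self):
        with pytest.warns(UserWarning):
            a = amplification_index_analytic(MeanFieldParams(w_sv=1.2, w_vs=1.2))
        assert a == math.inf

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        w_sv=st.floats(0.1, 0.95), w_vs=st.floats(0.1, 0.95),
        w_ss=st.floats(0.0, 0.5), w_vv=st.floats(0.0, 0.5),
        w_ps=st.floats(0.0, 2.0), w_pp=st.floats(0.0, 2.0),
    )
    def test_identity_with_slope_ratio(self, w_sv, w_vs, w_ss, w_vv, w_ps, w_pp):
        """A == log2(m_full / m_ref) identically over valid draws."""
        p = MeanFieldParams(w_sv=w_sv, w_vs=w_vs, w_ss=w_ss, w_vv=w_vv,
                            w_ps=w_ps, w_pp=w_pp)
        if (1 + w_ss) * (1 + w_vv) - w_sv * w_vs <= 1e-3:
            return
        a = amplification_index_analytic(p)
        assert a == pytest.approx(math.log2(slope_full(p) / slope_ref(p)), abs=1e-12)


class TestLinearizedSystem:
    def test_uncoupled_diagonal(self):
        p = MeanFieldParams(w_sv=0.0, w_vs=0.0, n=1, tau=0.01)
        m = build_linearized_system(p)
        assert np.allclose(m, -100.0 * np.eye(2))

    def test_recurrence_mode_eigenvalues(self):
        """n=2 with recurrence only: within-population eigenvalues
        (-1 +- w_r)/tau (per-synapse w_r = w_r_hat/(n-1))."""
        p = MeanFieldParams(w_sv=0.0, w_vs=0.0, w_ss=0.4, w_vv=0.4, n=2, tau=0.01)
        eig = np.sort(np.linalg.eigvals(build_linearized_system(p)).real)
        expected = np.sort([(-1 - 0.4) / 0.01] * 2 + [(-1 + 0.4) / 0.01] * 2)
        assert np.allclose(eig, expected)

    def test_adaptation_block_entries(self):
        p = MeanFieldParams(w_sv=0.0, w_vs=0.0, n=1, tau=0.01, b=0.5, tau_a=0.1)
        m = build_linearized_system(p, with_adaptation=True)
        assert m[1, 0] == pytest.approx(0.5 / 0.1)
        assert m[1, 1] == pytest.approx(-1 / 0.1)
        assert m[0, 1] == pytest.approx(-1 / 0.01)


class TestRegimeClassification:
    def test_attenuation_point(self):
        rep = classify_regime_theory(MeanFieldParams(w_sv=0.5, w_vs=0.5, b=0.0))
        assert rep.label == "attenuation"
        assert rep.amplification_index < 0

    def test_switch_condition(self):
        rep = classify_regime_theory(
            MeanFieldParams(w_sv=1.5, w_vs=1.5, b=0.2, tau_a=0.05))
        assert rep.label == "wta_switch"

    def test_oscillation_condition(self):
        rep = classify_regime_theory(
            MeanFieldParams(w_sv=1.3, w_vs=1.3, b=1.0, tau=0.01, tau_a=0.05))
        assert rep.label == "oscillation"

    def test_recurrence_pathological_labels(self):
        n = 5
        rep = classify_regime_theory(
            MeanFieldParams(w_sv=0.8, w_vs=0.8, w_ss=4.5, w_vv=4.5, b=0.0, n=n))
        assert rep.label == "wta_within_population"
        rep2 = classify_regime_theory(
            MeanFieldParams(w_sv=7.0, w_vs=7.0, w_ss=4.5, w_vv=4.5, b=0.0, n=n))
        assert rep2.label == "total_wta"

    def test_amplification_threshold_conventions(self):
        p = MeanFieldParams(w_sv=0.7, w_vs=0.7, b=0.0)
        a = amplification_index_analytic(p)
        assert 0 < a < 1
        assert classify_regime_theory(p, amplification_threshold=0.0).label == "amplification"
        assert classify_regime_theory(p, amplification_threshold=1.0).label == "attenuation"

    @pytest.mark.parametrize("b, tau_a, expected", [
        # strong adaptation: the first instability is the oscillation
        # onset at w_hat = 1 + tau/tau_a
        (0.4, 0.05, 1.2),
        # weak adaptation: no oscillation window, the onset is the switch
        # boundary at w_hat = b + 1
        (0.1, 0.05, 1.1),
    ])
    def test_instability_onset_bisection_matches_closed_form(self, b, tau_a, expected):
        """The first coexistence instability located by bisection on
        eigenvalue real parts coincides with the closed-form boundary
        (min of the switch and oscillation onsets) within 1e-6."""

        def max_re(w):
            p = MeanFieldParams(w_sv=w, w_vs=w, b=b, tau_a=tau_a, n=4)
            return np.max(np.linalg.eigvals(
                build_linearized_system(p, with_adaptation=True)).real)

        lo, hi = 1.0, 1.8
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if max_re(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(expected, abs=1e-6)


class TestOscillationFrequency:
    def test_printed_example(self):
        """w_hat=1.3, b=1, tau=10 ms, tau_a=50 ms: f = sqrt(8000-2500)/(4 pi)
        ~ 5.90 Hz, identically from eigenvalues and the closed form."""
        p = MeanFieldParams(w_sv=1.3, w_vs=1.3, b=1.0, tau=0.01, tau_a=0.05)
        f_expected = math.sqrt(8000.0 - 2500.0) / (4 * math.pi)
        assert oscillation_frequency_theory(p) == pytest.approx(f_expected, abs=1e-9)
        assert oscillation_frequency_theory(p, closed_form=True) == pytest.approx(
            f_expected, abs=1e-9)

    @pytest.mark.parametrize("w, b, tau_a", [
        (1.3, 1.0, 0.05), (1.3, 0.8, 0.1), (1.2, 1.5, 0.1),
    ])
    def test_eigen_route_equals_closed_form(self, w, b, tau_a):
        p = MeanFieldParams(w_sv=w, w_vs=w, b=b, tau=0.01, tau_a=tau_a)
        assert oscillation_frequency_theory(p) == pytest.approx(
            oscillation_frequency_theory(p, closed_form=True), abs=1e-9)

    def test_negative_discriminant_raises(self):
        p = MeanFieldParams(w_sv=1.4, w_vs=1.4, b=0.5, tau=0.01, tau_a=0.2)
        with pytest.raises(ValueError):
            oscillation_frequency_theory(p, closed_form=True)

    def test_monotone_in_b_and_tau_a(self):
        base = dict(w_sv=1.3, w_vs=1.3, tau=0.01)
        f_b = [oscillation_frequency_theory(MeanFieldParams(b=b, tau_a=0.05, **base))
               for b in (0.6, 1.0, 1.5)]
        assert f_b == sorted(f_b)
        f_ta = [oscillation_frequency_theory(MeanFieldParams(b=1.0, tau_a=ta, **base))
                for ta in (0.05, 0.1, 0.2)]
        assert f_ta == sorted(f_ta, reverse=True)


class TestWTAOnset:
    def test_critical_product_is_one(self):
        """Coexistence loses stability exactly where the analytic
        amplification index diverges: w_sv_hat * w_vs_hat = 1."""
        assert wta_onset_bisection(tol=1e-9) == pytest.approx(1.0, abs=1e-8)


class TestTransferAmplitude:
    def test_zero_frequency_equals_steady_slope(self):
        p = MeanFieldParams(w_sv=0.8, w_vs=0.8)
        assert transfer_amplitude_theory(p, 0.0, "full") == pytest.approx(slope_full(p))
        assert transfer_amplitude_theory(p, 0.0, "reference") == pytest.approx(slope_ref(p))

    def test_adaptation_creates_resonance(self):
        p = MeanFieldParams(w_sv=0.8, w_vs=0.8, b=0.8, tau_a=0.1)
        freqs = np.linspace(0.5, 30, 100)
        amps = [transfer_amplitude_theory(p, f, "full") for f in freqs]
        k = int(np.argmax(amps))
        assert 0 < k < len(freqs) - 1  # interior maximum
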