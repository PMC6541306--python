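"""Circuit construction: degree-regular connectivity, exact weight totals,
STF handling, background calibration and serialization."""

import numpy as np
import pytest

from somvip.circuit import (
    CircuitSpec,
    ConnectivityParams,
    PopulationLayout,
    SpecError,
    STFParams,
    assign_weights,
    build_circuit,
    build_connectivity,
    calibrate_background,
    configure_mismatch_circuit,
    rescale_for_stf,
    stf_steady_state,
)
from somvip.dynamics import simulate

from conftest import motif_spec


class TestConnectivity:
    def test_exact_in_degrees_full_circuit(self):
        spec = CircuitSpec(variant="full_circuit")
        adj = build_connectivity(spec, seed=0)
        for (post, pre), a in adj.items():
            p = spec.connectivity.prob[(post, pre)]
            n_pre = spec.layout.n(pre)
            k = int(round(p * n_pre))
            assert set(a.sum(axis=1)) == {k}, (post, pre)

    def test_out_degree_spread_at_most_one(self):
        spec = CircuitSpec(variant="full_circuit")
        adj = build_connectivity(spec, seed=3)
        for pair, a in adj.items():
            od = a.sum(axis=0)
            assert od.max() - od.min() <= 1, pair

    def test_no_autapses_within_class(self):
        spec = CircuitSpec(variant="full_circuit",
                           connectivity=ConnectivityParams().with_recurrence(0.5))
        adj = build_connectivity(spec, seed=0)
        for pair in (("P", "P"), ("S", "S"), ("V", "V"), ("D", "E")):
            assert not adj[pair].diagonal().any(), pair

    def test_fractional_expected_degree_rounds(self):
        # D<-S: p=0.55 with 10 SOM cells -> in-degree round(5.5) = 6
        spec = CircuitSpec(variant="full_circuit")
        adj = build_connectivity(spec, seed=0)
        assert set(adj[("D", "S")].sum(axis=1)) == {6}

    def test_deterministic_given_seed(self):
        spec = CircuitSpec(variant="interneuron_only")
        a1 = build_connectivity(spec, seed=7)
        a2 = build_connectivity(spec, seed=7)
        for pair in a1:
            assert np.array_equal(a1[pair], a2[pair])

    def test_zero_probability_gives_empty_adjacency(self):
        layout = PopulationLayout()
        conn = ConnectivityParams(
            prob={("S", "V"): 0.0}, total={("S", "V"): 0.0})
        adj = build_connectivity(layout, conn, seed=0, pairs=[("S", "V")])
        assert adj[("S", "V")].sum() == 0

    def test_inconsistent_strength_with_zero_degree_raises(self):
        layout = PopulationLayout()
        conn = ConnectivityParams(prob={("S", "V"): 0.0}, total={("S", "V"): 0.7})
        with pytest.raises(SpecError):
            build_connectivity(layout, conn, seed=0, pairs=[("S", "V")])


class TestWeights:
    def test_per_synapse_magnitude_and_sign(self):
        # total 0.7 over K=6 PV inputs -> magnitude 0.7/6, negative sign
        spec = CircuitSpec(variant="full_circuit")
        adj = build_connectivity(spec, seed=0)
        w = assign_weights(adj, spec.connectivity)
        mat = w[("E", "P")]
        nz = mat[mat != 0]
        assert np.allclose(nz, -0.7 / 6)
        assert w.total(("E", "P")) == pytest.approx(-0.7, abs=1e-15)

    def test_row_totals_exact_for_all_classes(self):
        spec = CircuitSpec(variant="full_circuit",
                           connectivity=ConnectivityParams().with_mutual_inhibition(0.9))
        c = build_circuit(spec, seed=1)
        for pair in c.weights.pairs():
            expected = spec.connectivity.total[pair]
            sign = -1 if pair[1] in ("P", "S", "V") else 1
            rows = c.weights[pair].sum(axis=1)
            assert np.allclose(rows, sign * expected, atol=1e-12), pair

    def test_population_scaling_preserves_totals(self):
        base = motif_spec(0.7)
        big = motif_spec(0.7, layout=PopulationLayout(size_multiplier=5))
        cb, cg = build_circuit(base, seed=0), build_circuit(big, seed=0)
        for pair in cb.weights.pairs():
            assert cg.weights.total(pair) == pytest.approx(cb.weights.total(pair))
            # per-synapse magnitude shrinks with the presynaptic pool
            assert cg.weights.in_degree[pair] > cb.weights.in_degree[pair]

    def test_rescale_for_stf_divides_mutual_weights(self):
        spec = motif_spec(0.7)
        adj = build_connectivity(spec, seed=0)
        w = assign_weights(adj, spec.connectivity)
        w2 = rescale_for_stf(w, STFParams(u_s=0.4, tau_f=0.2))
        assert w2.total(("S", "V")) == pytest.approx(-0.7 / 0.4)
        # initial response = weight * U_s equals the nominal total
        assert w2.total(("S", "V")) * 0.4 == pytest.approx(w.total(("S", "V")))

    def test_rescale_identity_without_stf(self):
        spec = motif_spec(0.9)
        w = assign_weights(build_connectivity(spec, seed=0), spec.connectivity)
        w2 = rescale_for_stf(w, STFParams(u_s=1.0))
        assert w2.total(("S", "V")) == pytest.approx(w.total(("S", "V")))


class TestSTFSteadyState:
    @pytest.mark.parametrize("u_s, tau_f, r, expected", [
        (0.4, 0.2, 0.0, 0.4),        # silent presynapse
        (1.0, 0.2, 7.3, 1.0),        # no facilitation
        (0.4, 0.2, 3.0, 0.64 / 1.24),  # hand arithmetic
    ])
    def test_values(self, u_s, tau_f, r, expected):
        assert stf_steady_state(u_s, tau_f, r) == pytest.approx(expected, rel=1e-12)

    def test_monotone_increasing_and_bounded(self):
        r = np.linspace(0, 100, 400)
        u = stf_steady_state(0.3, 0.15, r)
        assert np.all(np.diff(u) > 0)
        assert np.all((u >= 0.3) & (u < 1.0))


class TestCalibration:
    def test_isolated_unit(self):
        # no inputs, no adaptation: x = r0
        spec = motif_spec(0.0)
        c = build_circuit(spec, seed=0)
        assert np.allclose(c.background["S"], 3.0)
        assert np.allclose(c.background["V"], 3.0)

    def test_som_unit_with_mutual_inhibition(self):
        # b=0, w_sv=0.7, no STF: x = 3 + 0.7*3 = 5.1
        spec = motif_spec(0.7)
        c = build_circuit(spec, seed=0)
        assert np.allclose(c.background["S"], 5.1)

    def test_pv_background_interneuron_network(self):
        spec = CircuitSpec(variant="interneuron_only",
                           connectivity=ConnectivityParams().with_mutual_inhibition(0.7))
        c = build_circuit(spec, seed=0)
        # x_PV = 3 + 1.5*3 + 1.3*3
        assert np.allclose(c.background["P"], 11.4)

    def test_full_circuit_uses_printed_backgrounds(self):
        c = build_circuit(CircuitSpec(variant="full_circuit"), seed=0)
        assert np.allclose(c.background["E"], 17.5)
        assert np.allclose(c.background["D"], 21.0)
        for cls in ("P", "S", "V"):
            assert np.allclose(c.background[cls], 3.0)

    def test_wta_regime_warns(self):
        spec = motif_spec(1.5)
        adj = build_connectivity(spec, seed=0)
        w = assign_weights(adj, spec.connectivity)
        with pytest.warns(UserWarning, match="winner-take-all"):
            calibrate_background(spec, w)

    def test_calibrated_network_relaxes_to_r0(self, fig1_spec):
        # simulation from zero reaches the 3/s spontaneous state
        c = build_circuit(fig1_spec, seed=2)
        res = simulate(c, duration=2.0)
        for cls in ("r_p", "r_s", "r_v"):
            assert np.allclose(getattr(res.final_state, cls), 3.0, atol=1e-3)


class TestMismatchConfiguration:
    def test_tuned_pv_to_soma_strength(self):
        spec = configure_mismatch_circuit(CircuitSpec(variant="full_circuit"))
        assert spec.connectivity.total[("P", "S")] == 0.2
        assert spec.connectivity.total[("P", "P")] == 1.0
        assert spec.connectivity.total[("E", "P")] == pytest.approx(2.5)

    def test_pc_time_constant_increased_sixfold(self):
        spec = configure_mismatch_circuit(CircuitSpec(variant="full_circuit"))
        assert spec.pc.tau_e == pytest.approx(0.06)

    def test_requires_full_circuit(self):
        with pytest.raises(SpecError):
            configure_mismatch_circuit(CircuitSpec(variant="interneuron_only"))


class TestSerialization:
    def test_json_round_trip(self, fig1_spec):
        restored = CircuitSpec.from_json(fig1_spec.to_json())
        assert restored == fig1_spec

    def test_round_trip_preserves_variant_specifics(self):
        spec = motif_spec(1.2, b=0.5, tau_a=0.2,
                          layout=PopulationLayout(n_som=5, n_vip=5))
        assert CircuitSpec.from_json(spec.to_json()) == spec


class TestPopulationSizeInvariance:
    def test_meanfield_rates_independent_of_size(self):
        """With totals fixed, steady-state rates are identical for
        size multipliers 1 and 5."""
        r = {}
        for mult in (1, 5):
            spec = motif_spec(0.7, b=0.2,
                              layout=PopulationLayout(size_multiplier=mult))
            c = build_circuit(spec, seed=0)
            res = simulate(c, duration=1.5)
            r[mult] = (res.final_state.r_s.mean(), res.final_state.r_v.mean())
        assert r[1] == pytest.approx(r[5], abs=1e-9)
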