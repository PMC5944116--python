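import numpy as np
import pytest

from microdynet import (
    ChangeMatrix,
    NetworkTopology,
    PerturbationConfig,
    TrainingConfig,
    forward,
    init_model,
    recover_interactions_benchmark,
    relative_change,
    sensitivity_matrix,
    significant_network,
    simulate_dynamics,
)
from microdynet.sensitivity_network import (
    read_change_matrix,
    to_networkx,
    write_change_matrix,
)
from microdynet.synthetic_data import SimConfig, sign_recovery_benchmark_config
from microdynet.taxon_tables import CorePartition


class TestRelativeChange:
    def test_proportional_response_is_100(self):
        # output +5% under input +5%
        assert relative_change(0.2, 0.21, 0.1, 0.105) == pytest.approx(100.0)

    def test_unchanged_output_is_zero(self):
        assert relative_change(0.2, 0.2, 0.1, 0.105) == 0.0

    def test_hand_value(self):
        # (-0.05 / +0.05) * 100 = -100
        assert relative_change(0.2, 0.19, 0.1, 0.105) == pytest.approx(-100.0)

    def test_unchanged_input_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.2, 0.3, 0.1, 0.1)

    def test_zero_output_floored(self):
        val = relative_change(0.0, 0.001, 0.1, 0.105, epsilon_zero=1e-6)
        assert np.isfinite(val)


def _passthrough_model():
    """Each taxon input drives only its own output with elasticity exactly 1
    at the reference state (linear regime of every activation)."""
    topo = NetworkTopology(n_taxa=3, n_substrates=1)
    cfg = TrainingConfig(seed=0)
    model = init_model(topo, ("a", "b", "c"), ("s",), cfg)
    ref = np.array([0.2, 0.3, 0.4, 0.0])
    a = b = 0.01
    w = model.weights
    for k in w:
        w[k] = np.zeros_like(w[k])
    w["W1"][:3, :3] = np.eye(3) * a  # hidden1 has 4 nodes; use first 3
    w["W2"][:3, :3] = np.eye(3) * b
    h1_ref = np.tanh(a * ref[:3])
    w["b2"][:] = 0.0
    w["b2"][:3] = -b * h1_ref  # centre hidden2 at sigmoid(0) = 0.5
    # choose the output gain so x * dy/dx / y == 1 at the reference
    for j in range(3):
        dh2_dx = 0.25 * b * (1 - np.tanh(a * ref[j]) ** 2) * a
        c = 0.5 / (ref[j] * 0.25 * dh2_dx)
        w["W3"][j, j] = c
        w["b3"][j] = -c * 0.5  # centre output at sigmoid(0) = 0.5
    return model, ref


class TestSensitivityMatrix:
    def test_passthrough_diagonal_100(self):
        """An identity-like map yields ~100 on the diagonal, 0 elsewhere."""
        model, ref = _passthrough_model()
        config = PerturbationConfig(
            reference_input=ref, relative_range=0.01,
            n_perturbations=100, grid_mode=True, seed=1,
        )
        M = sensitivity_matrix(model, config).values
        for i in range(3):
            for j in range(3):
                expected = 100.0 if i == j else 0.0
                assert abs(M[i, j] - expected) < 1e-2, (i, j, M[i, j])

    def test_input_blind_model_all_zero(self):
        topo = NetworkTopology(n_taxa=3, n_substrates=1)
        model = init_model(topo, ("a", "b", "c"), ("s",), TrainingConfig(seed=2))
        model.weights["W1"] = np.zeros_like(model.weights["W1"])
        config = PerturbationConfig(
            reference_input=np.array([0.2, 0.3, 0.5, 1.0]), seed=3
        )
        M = sensitivity_matrix(model, config).values
        np.testing.assert_allclose(M, 0.0, atol=1e-12)

    def test_matches_loop_oracle(self):
        """Vectorised rows equal an independent per-perturbation loop that
        replays the same seeded draws through the relative-change formula."""
        topo = NetworkTopology(n_taxa=3, n_substrates=2)
        model = init_model(topo, ("a", "b", "c"), ("s1", "s2"),
                           TrainingConfig(seed=4, weight_init_range=0.5))
        ref = np.array([0.15, 0.35, 0.5, 1.0, 0.0])
        n = 50
        config = PerturbationConfig(reference_input=ref, n_perturbations=n,
                                    seed=5)
        M = sensitivity_matrix(model, config).values

        rng = np.random.default_rng(5)
        y0 = forward(model, ref)
        y0f = np.maximum(y0, config.epsilon_zero)
        oracle = np.zeros_like(M)
        for i in range(3):
            lo = ref[i] * (1 - config.relative_range)
            hi = ref[i] * (1 + config.relative_range)
            vals = rng.uniform(lo, hi, size=n)
            for j in range(3):
                acc = []
                for v in vals:
                    x = ref.copy()
                    x[i] = v
                    y = forward(model, x)
                    out_rel = (y[j] - y0[j]) / y0f[j]
                    in_rel = (v - ref[i]) / ref[i]
                    acc.append(out_rel / in_rel * 100)
                oracle[i, j] = np.mean(acc)
        for k in range(2):
            x = ref.copy()
            x[3 + k] = 1 - x[3 + k]
            y = forward(model, x)
            sgn = 1.0 if x[3 + k] > ref[3 + k] else -1.0
            oracle[3 + k] = (y - y0) / y0f / sgn * 100
        np.testing.assert_allclose(M, oracle, atol=1e-10, rtol=0)

    def test_reproducible_and_stable_in_n(self):
        topo = NetworkTopology(n_taxa=4, n_substrates=1)
        model = init_model(topo, tuple("abcd"), ("s",),
                           TrainingConfig(seed=6, weight_init_range=0.3))
        ref = np.array([0.3, 0.25, 0.25, 0.2, 0.0])
        m1 = sensitivity_matrix(model, PerturbationConfig(
            reference_input=ref, seed=7)).values
        m2 = sensitivity_matrix(model, PerturbationConfig(
            reference_input=ref, seed=7)).values
        np.testing.assert_array_equal(m1, m2)
        m4 = sensitivity_matrix(model, PerturbationConfig(
            reference_input=ref, n_perturbations=400, seed=8)).values
        # entries are means of ~bounded per-perturbation values; with 4x the
        # draws they should move well under the entry scale
        scale = np.abs(m1).max()
        assert np.abs(m1 - m4).max() < 0.2 * scale + 1e-9

    def test_zero_reference_abundance_flagged(self):
        topo = NetworkTopology(n_taxa=3, n_substrates=1)
        model = init_model(topo, ("a", "b", "c"), ("s",),
                           TrainingConfig(seed=9))
        ref = np.array([0.0, 0.4, 0.6, 0.0])
        matrix = sensitivity_matrix(model, PerturbationConfig(
            reference_input=ref, seed=10))
        assert "a" in matrix.flagged_rows
        assert np.isfinite(matrix.values).all()

    def test_small_perturbation_matches_analytic_jacobian(self):
        """On a single-path network the averaged relative change converges to
        the analytic elasticity x * dy/dx / y."""
        topo = NetworkTopology(n_taxa=1, n_substrates=0)
        model = init_model(topo, ("a",), (), TrainingConfig(seed=11))
        w = model.weights
        for name, val in [("W1", 1.2), ("W2", -0.8), ("W3", 1.5)]:
            w[name] = np.full_like(w[name], val)
        for name, val in [("b1", 0.1), ("b2", -0.2), ("b3", 0.3)]:
            w[name] = np.full_like(w[name], val)
        x = 0.4
        z1 = 1.2 * x + 0.1
        h1 = np.tanh(z1)
        z2 = -0.8 * h1 - 0.2
        h2 = 1 / (1 + np.exp(-z2))
        z3 = 1.5 * h2 + 0.3
        y = 1 / (1 + np.exp(-z3))
        dy_dx = (y * (1 - y)) * 1.5 * (h2 * (1 - h2)) * (-0.8) * (1 - h1 ** 2) * 1.2
        elasticity = x * dy_dx / y
        matrix = sensitivity_matrix(model, PerturbationConfig(
            reference_input=np.array([x]), relative_range=0.001,
            n_perturbations=100, grid_mode=True, seed=12))
        assert matrix.values[0, 0] == pytest.approx(100 * elasticity,
                                                    rel=1e-3)


class TestSignificantNetwork:
    def _matrix(self, values, n_sub=0):
        values = np.asarray(values, dtype=float)
        n_in, n_out = values.shape
        rows = tuple(f"t{i}" for i in range(n_in - n_sub)) + tuple(
            f"s{k}" for k in range(n_sub)
        )
        cols = tuple(f"t{j}" for j in range(n_out))
        return ChangeMatrix(rows, cols, values)

    def test_constant_matrix_no_edges(self):
        net = significant_network(self._matrix(np.full((4, 4), 2.5)))
        assert net.edges == []

    def test_single_extreme_entry(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(-1, 1, size=(10, 10))
        values[3, 7] = 1000.0
        net = significant_network(self._matrix(values))
        assert len(net.edges) == 1
        src, tgt, value, sign = net.edges[0]
        assert (src, tgt, sign) == ("t3", "t7", "direct")
        assert value == 1000.0

    def test_outbound_inbound_counts(self):
        values = np.zeros((8, 8))
        values[2, [0, 1, 3, 4, 5, 6]] = 500.0
        net = significant_network(self._matrix(values))
        assert net.outbound_count["t2"] == 6
        assert net.inbound_count["t2"] == 0
        assert sum(net.inbound_count.values()) == 6

    def test_sign_classification(self):
        values = np.zeros((10, 10))
        values[0, 1] = 800.0
        values[1, 2] = -900.0
        net = significant_network(self._matrix(values))
        signs = {(s, t): sign for s, t, _, sign in net.edges}
        assert signs[("t0", "t1")] == "direct"
        assert signs[("t1", "t2")] == "inverse"

    def test_monotone_shrink_with_multiplier(self):
        rng = np.random.default_rng(2)
        matrix = self._matrix(rng.normal(0, 50, size=(12, 12)))
        previous = None
        for k in (1.0, 2.0, 3.0):
            edges = {(s, t) for s, t, _, _ in
                     significant_network(matrix, sd_multiplier=k).edges}
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_core_flags_attached(self):
        values = np.zeros((10, 10))
        values[0, 1] = 700.0
        core = CorePartition(core_taxa={"t0"}, noncore_taxa={"t1", "t2"},
                             prevalence_threshold=1.0)
        net = significant_network(self._matrix(values), core)
        assert net.core_flags["t0"] is True
        assert net.core_flags["t1"] is False

    def test_networkx_round_trip(self):
        values = np.zeros((10, 10))
        values[0, 1] = 700.0
        g = to_networkx(significant_network(self._matrix(values)))
        assert g.has_edge("t0", "t1")
        assert g.edges["t0", "t1"]["sign"] == "direct"


class TestBenchmark:
    def test_zero_matrix_not_applicable(self):
        cfg = SimConfig(n_taxa=4, n_substrates=1, sampling_days=(0, 1, 2, 3),
                        replicates_per_timepoint=1, seed=1)
        ds = simulate_dynamics(cfg)
        topo = NetworkTopology(4, 1)
        out = recover_interactions_benchmark(
            ds, topo, TrainingConfig(seed=1, max_epochs=50), seed=1
        )
        assert out is None

    def test_deterministic(self):
        ds = simulate_dynamics(sign_recovery_benchmark_config(seed=2))
        topo = NetworkTopology(8, 6)
        cfg = TrainingConfig(seed=2, max_epochs=2000)
        a = recover_interactions_benchmark(ds, topo, cfg, seed=2)
        b = recover_interactions_benchmark(ds, topo, cfg, seed=2)
        assert a == b

    def test_strong_edge_signs_recovered(self):
        """Noise-free strong interactions are recovered with the right sign
        for at least 2/3 of edges in a majority of seeds."""
        topo = NetworkTopology(8, 6)
        passed = 0
        for seed in (1, 2, 3):
            ds = simulate_dynamics(sign_recovery_benchmark_config(seed=seed))
            frac = recover_interactions_benchmark(
                ds, topo, TrainingConfig(seed=seed), seed=seed
            )
            passed += frac >= 2 / 3
        assert passed >= 2


def test_change_matrix_file_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    matrix = ChangeMatrix(("a", "b", "s"), ("a", "b"),
                          rng.normal(size=(3, 2)))
    path = tmp_path / "cm.tsv"
    write_change_matrix(matrix, path)
    back = read_change_matrix(path)
    assert back.row_names == matrix.row_names
    np.testing.assert_allclose(back.values, matrix.values, rtol=1e-9)
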