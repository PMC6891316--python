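import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fatiguenet import (
    BrainNetwork, CorrelationMatrix, ValidationError,
    build_adjacency, clustering_coefficient, correlation_matrix,
    interval_midpoint, path_length_and_efficiency,
    sweep_threshold,
)
from fatiguenet.brain_network import DEFAULT_THRESHOLD_GRID
from conftest import all_graphs, brute_force_metrics


def corr_from(r):
    r = np.asarray(r, dtype=float)
    return CorrelationMatrix(labels=[f"C{i}" for i in range(len(r))], r=r)


def net_from(adj, T=0.5):
    adj = np.asarray(adj, dtype=np.int8)
    return BrainNetwork(labels=[f"C{i}" for i in range(len(adj))],
                        adjacency=adj, threshold=T)


def uniform_corr(n, value):
    r = np.full((n, n), float(value))
    np.fill_diagonal(r, 1.0)
    return corr_from(r)


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal((3, 500))
        r = correlation_matrix(x, ["a", "b", "c"]).r
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_negated_channel(self, rng):
        x = rng.standard_normal(500)
        r = correlation_matrix(np.vstack([x, -x]), ["a", "b"]).r
        assert r[0, 1] == pytest.approx(-1.0)

    def test_hand_evaluated_pair(self):
        # direct evaluation of the (n-1)-normalised product-moment formula
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        n = 4
        expected = (np.sum(x * y) - n * x.mean() * y.mean()) / (
            (n - 1) * x.std(ddof=1) * y.std(ddof=1))
        r = correlation_matrix(np.vstack([x, y]), ["a", "b"]).r
        assert r[0, 1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.6)

    def test_zero_variance_channel_named(self, rng):
        x = np.vstack([rng.standard_normal(100), np.full(100, 3.0)])
        with pytest.raises(ValidationError, match="FLAT"):
            correlation_matrix(x, ["OK", "FLAT"])

    def test_channel_permutation_equivariance(self, rng):
        x = rng.standard_normal((5, 400))
        labels = ["a", "b", "c", "d", "e"]
        perm = [3, 0, 4, 1, 2]
        r1 = correlation_matrix(x, labels).r
        r2 = correlation_matrix(x[perm], [labels[i] for i in perm]).r
        np.testing.assert_allclose(r2, r1[np.ix_(perm, perm)], atol=1e-12)


class TestAdjacency:
    def test_complete_graph_forced(self):
        net = build_adjacency(uniform_corr(14, 0.9), 0.3475)
        assert net.n_edges == 14 * 13 // 2 == 91

    def test_empty_graph_forced(self):
        net = build_adjacency(uniform_corr(14, 0.1), 0.3475)
        assert net.n_edges == 0

    def test_tie_breaks_to_no_edge(self):
        net = build_adjacency(uniform_corr(3, 0.3475), 0.3475)
        assert net.n_edges == 0

    def test_abs_corr_variant(self):
        net = build_adjacency(uniform_corr(3, -0.9), 0.5, abs_corr=True)
        assert net.n_edges == 3

    @pytest.mark.parametrize("T", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_outside_open_interval_rejected(self, T):
        with pytest.raises(ValidationError):
            build_adjacency(uniform_corr(3, 0.5), T)

    def test_raising_threshold_never_adds_edges(self, rng):
        x = rng.standard_normal((8, 300))
        corr = correlation_matrix(x, [f"C{i}" for i in range(8)])
        prev_edges, prev_G = None, None
        for T in (0.05, 0.2, 0.4, 0.6, 0.8):
            net = build_adjacency(corr, T)
            m = path_length_and_efficiency(net)
            if prev_edges is not None:
                assert net.n_edges <= prev_edges
                assert m.G <= prev_G + 1e-12
            prev_edges, prev_G = net.n_edges, m.G


class TestGraphMetrics:
    def test_complete_graph(self):
        adj = 1 - np.eye(14, dtype=np.int8)
        m = path_length_and_efficiency(net_from(adj))
        assert m.C == pytest.approx(1.0)
        assert m.L == pytest.approx(1.0)
        assert m.G == pytest.approx(1.0)

    def test_star_graph_has_no_triangles(self):
        adj = np.zeros((14, 14), dtype=np.int8)
        adj[0, 1:] = adj[1:, 0] = 1
        _, C = clustering_coefficient(net_from(adj))
        assert C == 0.0

    def test_empty_graph(self):
        m = path_length_and_efficiency(net_from(np.zeros((5, 5), dtype=np.int8)))
        assert m.G == 0.0
        assert np.isnan(m.L)
        assert m.n_finite_pairs == 0

    def test_three_node_path_efficiency(self):
        # a-b-c: ordered pairs 1,1,1,1,1/2,1/2 -> G = 5/6
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
        m = path_length_and_efficiency(net_from(adj))
        assert m.G == pytest.approx(5.0 / 6.0)
        assert m.L == pytest.approx((1 + 1 + 1 + 1 + 2 + 2) / 6.0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 11))
            a = (rng.random((n, n)) < rng.random()).astype(np.int8)
            a = np.triu(a, 1)
            a = a + a.T
            m = path_length_and_efficiency(net_from(a))
            c_bf, C_bf, L_bf, G_bf = brute_force_metrics(a)
            np.testing.assert_allclose(m.C_per_node, c_bf, atol=1e-12)
            assert m.C == pytest.approx(C_bf, abs=1e-12)
            assert m.G == pytest.approx(G_bf, abs=1e-12)
            if np.isnan(L_bf):
                assert np.isnan(m.L)
            else:
                assert m.L == pytest.approx(L_bf, abs=1e-12)

    def test_exhaustive_small_graphs(self):
        for a in all_graphs(4):
            m = path_length_and_efficiency(net_from(a))
            _, C_bf, L_bf, G_bf = brute_force_metrics(a)
            assert m.C == pytest.approx(C_bf, abs=1e-12)
            assert m.G == pytest.approx(G_bf, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 15 - 1), st.permutations(range(6)))
    def test_node_relabeling_equivariance(self, mask, perm):
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        a = np.zeros((6, 6), dtype=np.int8)
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                a[i, j] = a[j, i] = 1
        perm = list(perm)
        m1 = path_length_and_efficiency(net_from(a))
        m2 = path_length_and_efficiency(net_from(a[np.ix_(perm, perm)]))
        np.testing.assert_allclose(m2.C_per_node, m1.C_per_node[perm],
                                   atol=1e-12)
        assert m2.C == pytest.approx(m1.C)
        assert m2.G == pytest.approx(m1.G)


def metric_samples_significant_on(grid, sig_set, n_subjects=10, n_stages=7):
    """Build (n_T, n_subjects, n_stages) metric arrays in which stage 1
    differs from every other stage exactly at thresholds in ``sig_set``."""
    rng = np.random.default_rng(0)
    vals = np.empty((len(grid), n_subjects, n_stages))
    for ti, T in enumerate(grid):
        base = rng.normal(0.5, 0.01, size=(n_subjects, n_stages))
        if T in sig_set:
            base[:, 1:] += 0.5  # huge stage effect
        vals[ti] = base
    return vals


class TestThresholdSweep:
    def test_reported_interval_midpoint(self):
        # the reported significant interval [0.26, 0.435] selects T = 0.3475
        assert interval_midpoint(0.26, 0.435) == pytest.approx(0.3475)

    def test_constructed_interval_recovered(self):
        grid = DEFAULT_THRESHOLD_GRID
        sig = {t for t in grid if 0.235 <= t <= 0.46}
        vals = metric_samples_significant_on(grid, sig)
        res = sweep_threshold(vals, vals, thresholds=grid)
        assert res.significant_interval_C == (0.235, 0.46)
        assert res.significant_interval_G == (0.235, 0.46)
        assert res.selected_T == pytest.approx((0.235 + 0.46) / 2)

    def test_intersection_of_c_and_g_intervals(self):
        grid = DEFAULT_THRESHOLD_GRID
        c_vals = metric_samples_significant_on(
            grid, {t for t in grid if 0.26 <= t <= 0.46})
        g_vals = metric_samples_significant_on(
            grid, {t for t in grid if 0.21 <= t <= 0.435})
        res = sweep_threshold(c_vals, g_vals, thresholds=grid)
        assert res.selected_T == pytest.approx(interval_midpoint(0.26, 0.435))
        assert res.selected_T == pytest.approx(0.3475)

    def test_degenerate_single_point_interval(self):
        grid = DEFAULT_THRESHOLD_GRID
        vals = metric_samples_significant_on(grid, {0.31})
        res = sweep_threshold(vals, vals, thresholds=grid)
        assert res.significant_interval_C == (0.31, 0.31)
        assert res.selected_T == pytest.approx(0.31)

    def test_no_significant_point_flagged(self):
        grid = DEFAULT_THRESHOLD_GRID
        vals = metric_samples_significant_on(grid, set())
        res = sweep_threshold(vals, vals, thresholds=grid)
        assert res.empty
        assert res.selected_T is None
        assert res.significant_interval_C is None

    def test_stat_table_shape(self):
        grid = DEFAULT_THRESHOLD_GRID
        vals = metric_samples_significant_on(grid, set())
        res = sweep_threshold(vals, vals, thresholds=grid)
        # one row per threshold x comparison x metric
        assert len(res.stat_table) == len(grid) * 6 * 2

    def test_unsorted_grid_rejected(self):
        vals = np.zeros((2, 5, 7))
        with pytest.raises(ValidationError):
            sweep_threshold(vals, vals, thresholds=[0.4, 0.2])
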