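"""Co-occurrence networks: correlations, RMT threshold, indices, modularity."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from redunet import (
    AbundanceTable,
    build_network,
    correlation_matrix,
    greedy_modularity,
    index_panel,
    nnsd,
    prevalence_filter,
    rmt_threshold,
)
from redunet.network import GeneNetwork, modularity_q, spacing_gof


def _table(arr, cols):
    return AbundanceTable(pd.DataFrame(np.asarray(arr, dtype=float), columns=cols))


class TestCorrelationMatrix:
    def test_diagonal_and_exact_linearity(self):
        t = _table([[1, 2, 6], [2, 4, 4], [3, 6, 2]], ["x", "y", "z"])
        C = correlation_matrix(t, log_transform=False)
        assert C.loc["x", "x"] == pytest.approx(1.0)
        assert C.loc["x", "y"] == pytest.approx(1.0)     # y = 2x
        assert C.loc["x", "z"] == pytest.approx(-1.0)    # z = 8 - 2x

    def test_too_few_samples(self):
        t = _table([[1, 2], [3, 4]], ["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(t)

    def test_zero_variance_masked(self):
        t = _table([[1, 5], [2, 5], [3, 5]], ["a", "flat"])
        C = correlation_matrix(t, log_transform=False)
        assert np.isnan(C.loc["a", "flat"])
        assert C.loc["flat", "flat"] == pytest.approx(1.0)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random(10)
        t = _table(np.column_stack([x, np.exp(3 * x)]), ["x", "ex"])
        C = correlation_matrix(t, method="spearman", log_transform=False)
        assert C.loc["x", "ex"] == pytest.approx(1.0)

    def test_prevalence_filter(self):
        t = _table([[1, 0], [2, 0], [0, 0], [3, 1]], ["common", "rare"])
        out = prevalence_filter(t, 0.5)
        assert out.features == ["common"]


class TestNNSD:
    def test_equispaced_spectrum_unit_spacings(self):
        s = nnsd(np.arange(100, dtype=float))
        assert np.allclose(s, 1.0, atol=1e-6)

    def test_mean_one_normalization(self):
        rng = np.random.default_rng(1)
        s = nnsd(np.sort(rng.uniform(0, 50, 200)))
        assert s.mean() == pytest.approx(1.0, abs=1e-6)

    def test_too_few_eigenvalues(self):
        with pytest.raises(ValueError, match="30"):
            nnsd(np.arange(10, dtype=float))

    def test_goe_wigner_vs_poisson(self):
        """Classic RMT check: a GOE spectrum follows the Wigner surmise, an
        independent (uniform) spectrum follows Poisson."""
        rng = np.random.default_rng(0)
        M = rng.normal(size=(500, 500))
        goe = np.linalg.eigvalsh((M + M.T) / np.sqrt(2 * 500))
        s_goe = nnsd(goe)
        chi_p, _ = spacing_gof(s_goe, "poisson")
        chi_w, p_w = spacing_gof(s_goe, "wigner")
        assert chi_w < chi_p and p_w > 0.05

        s_u = nnsd(np.sort(rng.uniform(0, 100, 500)))
        chi_p2, p_p2 = spacing_gof(s_u, "poisson")
        chi_w2, _ = spacing_gof(s_u, "wigner")
        assert chi_p2 < chi_w2 and p_p2 > 0.05


def two_block_corr(seed, n_genes=40, n_samples=40, load=0.95):
    rng = np.random.default_rng(seed)
    cols = {}
    for b in range(2):
        f = rng.normal(size=n_samples)
        for i in range(n_genes):
            cols[f"b{b}_g{i:02d}"] = load * f + np.sqrt(1 - load ** 2) * rng.normal(size=n_samples)
    return pd.DataFrame(cols).corr()


class TestRmtThreshold:
    def test_two_block_separation(self):
        """The selected threshold separates two planted independent blocks."""
        corr = two_block_corr(0)
        thr = rmt_threshold(corr)
        net = build_network(corr, thr)
        cross = sum(1 for u, v in net.graph.edges if u[:2] != v[:2])
        assert cross == 0 and net.n_links > 0

    def test_feature_order_invariance(self):
        corr = two_block_corr(1)
        thr1 = rmt_threshold(corr)
        rng = np.random.default_rng(5)
        perm = rng.permutation(corr.shape[0])
        corr_p = corr.iloc[perm, perm]
        assert rmt_threshold(corr_p) == pytest.approx(thr1)

    def test_pure_noise_low_threshold(self):
        """Independent features: no structure above the noise floor, so the
        scan runs deep and returns a near-floor cutoff."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(200, 60)))
        thr = rmt_threshold(X.corr())
        assert thr <= 0.3

    def test_identity_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-isolated"):
            rmt_threshold(np.eye(50))


class TestBuildNetwork:
    def test_triangle(self):
        C = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        net = build_network(C, 0.9)
        assert net.n_nodes == 3 and net.n_links == 3

    def test_threshold_above_max_errors(self):
        C = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="no edge survives"):
            build_network(C, 0.9)

    def test_absolute_value_rule_keeps_negative_edges(self):
        C = pd.DataFrame([[1.0, -0.95], [-0.95, 1.0]], index=["a", "b"], columns=["a", "b"])
        net = build_network(C, 0.9)
        assert net.n_links == 1
        assert net.graph.edges["a", "b"]["sign"] == -1


def _net(g):
    return GeneNetwork(g, threshold=0.5)


class TestIndexPanel:
    def test_complete_graph_k4(self):
        p = index_panel(_net(nx.complete_graph(4)))
        assert (p.avgK, p.avgCC, p.GD, p.E, p.HD) == pytest.approx((3, 1, 1, 1, 1))

    def test_path_p3(self):
        p = index_panel(_net(nx.path_graph(3)))
        assert p.avgK == pytest.approx(4 / 3)
        assert p.GD == pytest.approx(4 / 3)
        assert p.E == pytest.approx((1 + 1 + 0.5) / 3)
        assert p.HD == pytest.approx(1.2)

    def test_two_disjoint_edges(self):
        g = nx.Graph([(0, 1), (2, 3)])
        p = index_panel(_net(g))
        assert p.GD == pytest.approx(1.0)          # connected pairs only
        assert p.E == pytest.approx(1 / 3)         # (2*1 + 4*0) / 6
        assert p.HD == pytest.approx(3.0)

    def test_hd_times_e_identity_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.4, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            p = index_panel(_net(g))
            if p.E > 0:
                assert p.HD * p.E == pytest.approx(1.0, abs=1e-9)
            assert p.avgK == pytest.approx(2 * p.n_links / p.n_nodes)

    def test_edge_addition_monotonicity(self):
        """On a connected graph, adding an edge never decreases avgK and never
        increases GD.  (On disconnected graphs GD may rise: a bridging edge
        pulls distant newly-connected pairs into the connected-pairs mean.)"""
        rng = np.random.default_rng(4)
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.45, seed=int(rng.integers(1e6)))
            if not nx.is_connected(g):
                continue
            p0 = index_panel(_net(g))
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[rng.integers(len(non_edges))]
            g2 = g.copy()
            g2.add_edge(u, v)
            p1 = index_panel(_net(g2))
            assert p1.avgK >= p0.avgK - 1e-12
            if p0.GD is not None and p1.GD is not None:
                assert p1.GD <= p0.GD + 1e-12


def brute_force_best_q(g):
    """Exhaustive search over all set partitions (graphs <= 8 nodes)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(nodes):
        q = modularity_q(g, [set(p) for p in part])
        best = max(best, q)
    return best


class TestGreedyModularity:
    def test_two_disconnected_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        partition, q = greedy_modularity(_net(g))
        assert q == pytest.approx(0.5)
        assert sorted(map(sorted, partition)) == [[0, 1, 2], [3, 4, 5]]

    def test_single_edge(self):
        partition, q = greedy_modularity(_net(nx.Graph([(0, 1)])))
        assert len(partition) == 1 and q == pytest.approx(0.0)

    def test_matches_networkx_q(self):
        """modularity_q agrees with the networkx implementation (independent
        oracle) for arbitrary partitions of random graphs."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            labels = rng.integers(0, 3, size=15)
            part = [set(np.flatnonzero(labels == k)) for k in range(3)]
            part = [p for p in part if p]
            assert modularity_q(g, part) == pytest.approx(
                nx.community.modularity(g, part, weight=None))
        g = nx.karate_club_graph()
        partition, q = greedy_modularity(_net(g))
        assert q == pytest.approx(nx.community.modularity(g, partition, weight=None))

    @pytest.mark.parametrize("builder", [
        lambda: nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]),
        lambda: nx.complete_graph(4),
        lambda: nx.path_graph(7),
        lambda: nx.cycle_graph(5),
        lambda: nx.star_graph(5),
        lambda: nx.Graph([(0, 1), (2, 3), (4, 5), (6, 7)]),
        lambda: nx.barbell_graph(3, 1),
        lambda: nx.complete_bipartite_graph(2, 3),
        lambda: nx.lollipop_graph(4, 3),
        lambda: nx.wheel_graph(6),
        lambda: nx.hypercube_graph(3),
    ])
    def test_equals_exhaustive_optimum(self, builder):
        """Greedy Q equals the brute-force maximum over all partitions."""
        g = builder()
        _, q = greedy_modularity(_net(g))
        assert q == pytest.approx(brute_force_best_q(g), abs=1e-12)

    def test_planted_two_block_recovery(self):
        """Greedy recovers planted blocks (adjusted Rand > 0.9 on average)."""
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(0)
        scores = []
        for _ in range(20):
            g = nx.stochastic_block_model(
                [20, 20], [[0.9, 0.02], [0.02, 0.9]], seed=int(rng.integers(1e6)))
            partition, _ = greedy_modularity(_net(g))
            labels = np.empty(40, dtype=int)
            for k, comm in enumerate(partition):
                for node in comm:
                    labels[node] = k
            truth = np.array([0] * 20 + [1] * 20)
            scores.append(adjusted_rand_score(truth, labels))
        assert np.mean(scores) > 0.9
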