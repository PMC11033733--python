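import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from assemblage.io_core import FeatureTable
from assemblage.networks import (
    build_network,
    compare_degree_distributions,
    ivi,
    top_influential,
    topology,
)


def table_from_columns(cols, sample_prefix="s"):
    counts = np.column_stack(cols)
    return FeatureTable(
        counts,
        [f"{sample_prefix}{i}" for i in range(counts.shape[0])],
        [f"t{j}" for j in range(counts.shape[1])],
    )


class TestBuildNetwork:
    def test_perfect_rank_order_edge(self):
        # equal sample totals keep relative-abundance ranks identical
        a = np.arange(1, 11)
        b = np.arange(2, 12)
        filler = 100 - a - b
        net = build_network(table_from_columns([a, b, filler]))
        assert net.has_edge("t0", "t1")
        assert net["t0"]["t1"]["spearman_r"] == pytest.approx(1.0)

    def test_boundary_r_excluded(self):
        # ranks engineered so spearman r = 0.6 exactly; strict > excludes
        x = np.array([1, 2, 3, 4, 5])
        y = np.array([2, 1, 5, 3, 4])
        filler = 20 - x - y
        ft = table_from_columns([x, y, filler])
        r = stats.spearmanr(x, y).statistic
        assert r == pytest.approx(0.6)
        net = build_network(ft, r_min=0.6, p_max=1.0)
        assert not net.has_edge("t0", "t1")

    def test_noise_false_edge_rate(self, rng):
        counts = rng.integers(1, 1000, size=(30, 20))
        ft = FeatureTable(counts, [f"s{i}" for i in range(30)], [f"t{j}" for j in range(20)])
        net = build_network(ft)
        assert net.number_of_edges() <= 0.05 * math.comb(20, 2)

    def test_too_few_samples(self, rng):
        counts = rng.integers(1, 9, size=(3, 5))
        ft = FeatureTable(counts, list("abc"), [f"t{j}" for j in range(5)])
        with pytest.raises(ValueError):
            build_network(ft)

    def test_constant_taxon_excluded(self, rng):
        a = np.arange(1, 11)
        const = np.full(10, 5)
        filler = 50 - a - const
        with pytest.warns(UserWarning, match="constant"):
            net = build_network(table_from_columns([a, const, filler]), r_min=0.0)
        assert "t1" not in net.nodes

    def test_sample_order_invariance(self, rng):
        counts = rng.integers(1, 50, size=(12, 8))
        ft = FeatureTable(counts, [f"s{i}" for i in range(12)], [f"t{j}" for j in range(8)])
        net1 = build_network(ft, r_min=0.3)
        perm = rng.permutation(12)
        ft2 = FeatureTable(counts[perm], [f"s{i}" for i in perm], list(ft.taxon_ids))
        net2 = build_network(ft2, r_min=0.3)
        assert set(net1.edges) == set(net2.edges)


class TestTopology:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        t = topology(g, seed=0)
        assert t.modularity == pytest.approx(0.5)
        assert t.clustering_coefficient == pytest.approx(1.0)
        assert t.average_degree == pytest.approx(2.0)

    def test_triangle(self):
        t = topology(nx.complete_graph(3), seed=0)
        assert t.clustering_coefficient == pytest.approx(1.0)
        assert t.average_degree == pytest.approx(2.0)

    def test_star(self):
        t = topology(nx.star_graph(5), seed=0)
        assert t.clustering_coefficient == pytest.approx(0.0)
        assert t.average_degree == pytest.approx(10 / 6)

    def test_empty(self):
        t = topology(nx.Graph(), seed=0)
        assert np.isnan(t.modularity)
        assert t.n_nodes == 0

    def test_brute_force_small_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 7))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            t = topology(g, seed=1)
            assert t.average_degree == pytest.approx(
                2 * g.number_of_edges() / g.number_of_nodes()
            )
            # brute-force local clustering
            cc = []
            for v in g.nodes:
                nb = list(g.neighbors(v))
                k = len(nb)
                if k < 2:
                    cc.append(0.0)
                    continue
                links = sum(
                    1
                    for i in range(k)
                    for j in range(i + 1, k)
                    if g.has_edge(nb[i], nb[j])
                )
                cc.append(2 * links / (k * (k - 1)))
            assert t.clustering_coefficient == pytest.approx(float(np.mean(cc)))


class TestKS:
    def test_identical_networks(self):
        g = nx.path_graph(6)
        d, p = compare_degree_distributions(g, g)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = nx.Graph([(0, 1), (2, 3)])  # degrees all 1
        b = nx.complete_graph(6)  # degrees all 5
        d, _ = compare_degree_distributions(a, b)
        assert d == pytest.approx(1.0)

    def test_matches_manual_ecdf(self):
        reg = nx.cycle_graph(6)  # degrees 2,2,2,2,2,2
        hub = nx.star_graph(5)  # degrees 5,1,1,1,1,1
        d, _ = compare_degree_distributions(reg, hub)
        d_oracle = stats.ks_2samp([2] * 6, [5, 1, 1, 1, 1, 1]).statistic
        assert d == pytest.approx(d_oracle)

    def test_small_network_errors(self):
        g = nx.Graph()
        g.add_node(0)
        with pytest.raises(ValueError):
            compare_degree_distributions(g, nx.path_graph(3))

    def test_clustering_property(self):
        a = nx.complete_graph(5)
        b = nx.star_graph(4)
        d, _ = compare_degree_distributions(a, b, property="clustering")
        assert d == pytest.approx(1.0)


class TestIVI:
    def test_star_center_is_one(self):
        star = nx.star_graph(8)
        s = ivi(star)
        assert s[0] == pytest.approx(1.0)
        leaves = s.drop(0)
        assert (leaves == leaves.iloc[0]).all()
        assert leaves.iloc[0] == pytest.approx(leaves.min())
        assert s.max() == 1.0

    def test_complete_graph_all_equal(self):
        s = ivi(nx.complete_graph(5))
        assert (s == 1.0).all()

    def test_two_node_edge(self):
        s = ivi(nx.path_graph(2))
        assert s[0] == s[1]

    def test_bounds(self):
        g = nx.barbell_graph(4, 2)
        s = ivi(g)
        assert (s >= 0).all() and (s <= 1).all()
        assert s.max() == 1.0

    def test_isomorphism_invariance(self):
        g = nx.barbell_graph(3, 1)
        mapping = {v: f"x{v}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        sg = ivi(g)
        sh = ivi(h)
        for v in g.nodes:
            assert sg[v] == pytest.approx(sh[f"x{v}"])

    def test_isolated_node_errors(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        with pytest.raises(ValueError):
            ivi(g)


class TestTopInfluential:
    def test_ceil_count(self):
        g = nx.gnp_random_graph(25, 0.3, seed=1)
        g.remove_nodes_from(list(nx.isolates(g)))
        while g.number_of_nodes() < 25:
            g.add_edge(g.number_of_nodes(), 0)
        s = ivi(g)
        assert len(top_influential(s, g, fraction=0.10)) == 3

    def test_all_tied_lexicographic(self):
        g = nx.relabel_nodes(nx.complete_graph(5), {i: c for i, c in enumerate("edcba")})
        s = ivi(g)
        top = top_influential(s, g, fraction=0.4)
        assert top == ["a", "b"]

    def test_star_center_included(self):
        star = nx.star_graph(9)
        s = ivi(star)
        assert 0 in top_influential(s, star, fraction=0.10)

    def test_bad_fraction(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            top_influential(ivi(g), g, fraction=0.0)
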