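import networkx as nx
import numpy as np
import pytest

from dream import moa
from dream.dataio import DrugRecord, GeneNetwork
from oracles import im_trapezoid


def net_from(edges, nodes=()):
    return GeneNetwork.from_edges(edges, nodes=nodes)


def random_network(rng, nodes, p=0.4):
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j], float(rng.random())))
    return net_from(edges, nodes=nodes)


class TestAlign:
    def test_identical_graphs_align_identically(self):
        g = net_from([("A", "B"), ("B", "C")])
        pair = moa.align_graphs(g, g)
        np.testing.assert_array_equal(pair.a, pair.b)

    def test_union_universe_pads_missing_nodes(self):
        g1 = net_from([("A", "B")])
        g2 = net_from([("B", "C")])
        pair = moa.align_graphs(g1, g2)
        assert pair.nodes == ["A", "B", "C"]
        assert pair.a[:, pair.nodes.index("C")].sum() == 0  # C isolated in g1

    def test_disjoint_node_sets_embed_block_diagonally(self):
        g1 = net_from([("A", "B")])
        g2 = net_from([("C", "D")])
        pair = moa.align_graphs(g1, g2)
        ia, ib = pair.nodes.index("A"), pair.nodes.index("B")
        ic, id_ = pair.nodes.index("C"), pair.nodes.index("D")
        assert pair.a[ia, ib] == 1 and pair.a[ic, id_] == 0
        assert pair.b[ic, id_] == 1 and pair.b[ia, ib] == 0

    def test_two_empty_graphs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            moa.align_graphs(GeneNetwork(), GeneNetwork())


class TestHamming:
    def test_identity(self):
        g = net_from([("A", "B", 0.5)])
        assert moa.hamming(moa.align_graphs(g, g)) == 0.0

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_empty_vs_complete_is_one(self, n):
        nodes = [f"n{i}" for i in range(n)]
        empty = net_from([], nodes=nodes)
        comp = GeneNetwork(nx.complete_graph(nodes))
        assert moa.hamming(moa.align_graphs(empty, comp)) == 1.0

    def test_two_of_six_pairs_differ(self):
        nodes = ["a", "b", "c", "d"]
        g1 = net_from([("a", "b"), ("c", "d")], nodes=nodes)
        g2 = net_from([("a", "b"), ("a", "c"), ("c", "d"), ("b", "d")], nodes=nodes)
        assert moa.hamming(moa.align_graphs(g1, g2)) == pytest.approx(2 / 6)


class TestIpsenMikhailov:
    def test_identical_spectra_give_zero(self):
        g = net_from([("A", "B"), ("B", "C"), ("C", "A")])
        assert moa.ipsen_mikhailov(moa.align_graphs(g, g)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n", [5, 10])
    def test_gamma_calibration_puts_empty_complete_at_one(self, n):
        nodes = [f"n{i}" for i in range(n)]
        empty = net_from([], nodes=nodes)
        comp = GeneNetwork(nx.complete_graph(nodes))
        im = moa.ipsen_mikhailov(moa.align_graphs(empty, comp), gamma=moa.find_gamma(n))
        assert abs(im - 1.0) < 1e-6

    def test_path_vs_star_matches_dense_grid_oracle(self):
        path = net_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        star = net_from([("a", "b"), ("a", "c"), ("a", "d"), ("a", "e")])
        pair = moa.align_graphs(path, star)
        gamma = moa.find_gamma(5)
        im = moa.ipsen_mikhailov(pair, gamma=gamma)
        oracle = im_trapezoid(
            moa.laplacian_frequencies(pair.a), moa.laplacian_frequencies(pair.b), gamma
        )
        assert im == pytest.approx(oracle, abs=1e-5)

    def test_isomorphic_relabeling_leaves_im_unchanged(self, rng):
        nodes = [f"n{i}" for i in range(7)]
        g1 = random_network(rng, nodes)
        g2 = random_network(rng, nodes)
        relabel = dict(zip(nodes, [f"m{i}" for i in range(7)]))
        h1 = GeneNetwork(nx.relabel_nodes(g1.graph, relabel))
        h2 = GeneNetwork(nx.relabel_nodes(g2.graph, relabel))
        im_a = moa.ipsen_mikhailov(moa.align_graphs(g1, g2))
        im_b = moa.ipsen_mikhailov(moa.align_graphs(h1, h2))
        assert im_a == pytest.approx(im_b, abs=1e-9)

    def test_nonpositive_gamma_rejected(self):
        g = net_from([("A", "B")])
        with pytest.raises(ValueError, match="gamma"):
            moa.ipsen_mikhailov(moa.align_graphs(g, g), gamma=0.0)


class TestFindGamma:
    def test_deterministic_across_calls(self):
        assert moa.find_gamma(6) == moa.find_gamma(6)

    def test_bisection_agrees_with_grid_scan(self):
        n = 6
        gamma = moa.find_gamma(n)
        w_empty = np.zeros(n - 1)
        w_comp = np.full(n - 1, np.sqrt(n))
        # two-stage scan of |IM(gamma) - 1|: coarse pass, then a refined window
        coarse = np.linspace(1e-4, 10.0, 1001)
        errs = [abs(im_trapezoid(w_empty, w_comp, g, n_points=3001) - 1.0) for g in coarse]
        center = coarse[int(np.argmin(errs))]
        fine = np.linspace(center - 0.02, center + 0.02, 401)
        errs = [abs(im_trapezoid(w_empty, w_comp, g, n_points=20001) - 1.0) for g in fine]
        assert abs(fine[int(np.argmin(errs))] - gamma) < 1e-3

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            moa.find_gamma(1)


class TestHim:
    def test_identity(self):
        g = net_from([("A", "B"), ("B", "C")])
        assert moa.him(moa.align_graphs(g, g)) == pytest.approx(0.0, abs=1e-9)

    def test_empty_vs_complete_is_one(self):
        nodes = [f"n{i}" for i in range(6)]
        empty = net_from([], nodes=nodes)
        comp = GeneNetwork(nx.complete_graph(nodes))
        assert moa.him(moa.align_graphs(empty, comp)) == pytest.approx(1.0, abs=1e-5)

    def test_composition_from_components(self):
        nodes = ["a", "b", "c", "d"]
        g1 = net_from([("a", "b"), ("c", "d")], nodes=nodes)
        g2 = net_from([("a", "b"), ("a", "c"), ("c", "d"), ("b", "d")], nodes=nodes)
        pair = moa.align_graphs(g1, g2)
        h = moa.hamming(pair)
        im = moa.ipsen_mikhailov(pair)
        assert moa.him(pair) == pytest.approx(np.sqrt(h**2 + im**2) / np.sqrt(2))

    def test_xi_limits_recover_components(self, rng):
        nodes = [f"n{i}" for i in range(6)]
        g1, g2 = random_network(rng, nodes), random_network(rng, nodes)
        pair = moa.align_graphs(g1, g2)
        assert moa.him(pair, xi=1e-8) == pytest.approx(moa.hamming(pair), abs=1e-4)
        assert moa.him(pair, xi=1e8) == pytest.approx(moa.ipsen_mikhailov(pair), abs=1e-4)

    def test_bounds_and_symmetry(self, rng):
        nodes = [f"n{i}" for i in range(8)]
        for _ in range(5):
            g1, g2 = random_network(rng, nodes), random_network(rng, nodes)
            d12 = moa.him(moa.align_graphs(g1, g2))
            d21 = moa.him(moa.align_graphs(g2, g1))
            assert 0.0 <= d12 <= 1.0
            assert d12 == pytest.approx(d21, abs=1e-9)


class TestMoaMatrix:
    def _drugs(self, rng, n=3):
        nodes = [f"n{i}" for i in range(6)]
        return [
            DrugRecord(f"d{i}", None, set(), random_network(rng, nodes)) for i in range(n)
        ]

    def test_identical_networks_give_zero_offdiagonal(self):
        g = net_from([("A", "B")])
        drugs = [DrugRecord("d1", None, set(), g), DrugRecord("d2", None, set(), g)]
        m = moa.moa_matrix(drugs)
        assert m.loc("d1", "d2") == pytest.approx(0.0, abs=1e-9)

    def test_matrix_symmetric_with_zero_diagonal(self, rng):
        m = moa.moa_matrix(self._drugs(rng))
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 0.0)

    def test_entries_equal_pairwise_him(self, rng):
        drugs = self._drugs(rng)
        m = moa.moa_matrix(drugs)
        for i in range(3):
            for j in range(i + 1, 3):
                pair = moa.align_graphs(
                    drugs[i].perturbational_network, drugs[j].perturbational_network
                )
                assert m.loc(drugs[i].drug_id, drugs[j].drug_id) == pytest.approx(
                    moa.him(pair), abs=1e-12
                )

    def test_drug_without_network_is_reported(self):
        drugs = [DrugRecord("d1", None, set(), net_from([("A", "B")])), DrugRecord("d2")]
        with pytest.raises(ValueError, match="d2"):
            moa.moa_matrix(drugs)
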