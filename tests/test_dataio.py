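import numpy as np
import pytest

from dream import dataio
from dream.dataio import DistanceMatrix, ExpressionDataset, FrontEntry, GeneNetwork


def write(path, text):
    path.write_text(text)
    return path


class TestReadExpression:
    def make_files(self, tmp_path, matrix, annotation):
        return (
            write(tmp_path / "expr.tsv", matrix),
            write(tmp_path / "annot.tsv", annotation),
        )

    def test_basic_load(self, tmp_path):
        expr, annot = self.make_files(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t5\t6\t7\t8\ng3\t0\t0\t1\t1\n",
            "sample\tcondition\ns1\tdisease\ns2\tdisease\ns3\tcontrol\ns4\tcontrol\n",
        )
        ds = dataio.read_expression(expr, annot)
        assert ds.values.shape == (3, 4)
        assert ds.condition == ["disease", "disease", "control", "control"]

    def test_unmatched_sample_is_named_in_error(self, tmp_path):
        expr, annot = self.make_files(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n",
            "sample\tcondition\ns1\tdisease\ns2\tdisease\ns3\tcontrol\n",
        )
        with pytest.raises(ValueError, match="s4"):
            dataio.read_expression(expr, annot)

    def test_duplicate_gene_keeps_max_variance_row(self, tmp_path):
        # g1 appears twice: variances 1.0 (1,2,3,4 scaled) vs 4.0
        expr, annot = self.make_files(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\n"
            "g1\t1\t2\t1\t2\n"  # var 1/3
            "g1\t0\t4\t0\t4\n"  # var 16/3
            "g2\t1\t1\t2\t2\n",
            "sample\tcondition\ns1\tdisease\ns2\tdisease\ns3\tcontrol\ns4\tcontrol\n",
        )
        ds = dataio.read_expression(expr, annot)
        assert ds.n_genes == 2
        row = ds.values[ds.gene_ids.index("g1")]
        assert row.tolist() == [0, 4, 0, 4]

    def test_missing_values_dropped(self, tmp_path):
        expr, annot = self.make_files(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\ng1\t1\t\t3\t4\ng2\t1\t2\t3\t4\ng3\t1\t2\t3\t4\n",
            "sample\tcondition\ns1\tdisease\ns2\tdisease\ns3\tcontrol\ns4\tcontrol\n",
        )
        ds = dataio.read_expression(expr, annot)
        assert ds.gene_ids == ["g2", "g3"]

    def test_fewer_than_two_samples_per_condition_rejected(self, tmp_path):
        expr, annot = self.make_files(
            tmp_path,
            "gene\ts1\ts2\ts3\ng1\t1\t2\t3\ng2\t1\t2\t3\ng3\t1\t2\t3\n",
            "sample\tcondition\ns1\tdisease\ns2\tcontrol\ns3\tcontrol\n",
        )
        with pytest.raises(ValueError, match="at least 2"):
            dataio.read_expression(expr, annot)


class TestReadNetwork:
    def test_duplicate_edge_keeps_max_weight(self, tmp_path):
        p = write(tmp_path / "net.tsv", "A\tB\t0.5\nB\tA\t0.7\n")
        net = dataio.read_network(p)
        assert net.edges() == [("A", "B", 0.7)]

    def test_self_loop_dropped(self, tmp_path):
        p = write(tmp_path / "net.tsv", "A\tA\t1.0\n")
        net = dataio.read_network(p)
        assert net.n_edges == 0

    def test_path_graph(self, tmp_path):
        p = write(tmp_path / "net.tsv", "A\tB\nB\tC\n")
        net = dataio.read_network(p)
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.weight("A", "B") == 1.0

    def test_out_of_range_weight_errors_unless_rescaled(self, tmp_path):
        p = write(tmp_path / "net.tsv", "A\tB\t2.0\nB\tC\t1.0\n")
        with pytest.raises(ValueError, match="rescale"):
            dataio.read_network(p)
        net = dataio.read_network(p, rescale=True)
        assert net.weight("A", "B") == 1.0 and net.weight("B", "C") == 0.0

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("A", "B", weight=0.5)
        g.add_edge("B", "C", weight=1.0)
        nx.write_graphml(g, tmp_path / "net.graphml")
        net = dataio.read_network(tmp_path / "net.graphml")
        assert net.edges() == [("A", "B", 0.5), ("B", "C", 1.0)]

    def test_edge_list_order_permutation_gives_same_object(self, tmp_path):
        p1 = write(tmp_path / "n1.tsv", "A\tB\t0.5\nB\tC\t0.25\n")
        p2 = write(tmp_path / "n2.tsv", "C\tB\t0.25\nB\tA\t0.5\n")
        assert dataio.read_network(p1) == dataio.read_network(p2)


class TestDrugLibrary:
    def test_targets_parsed(self, tmp_path):
        p = write(
            tmp_path / "lib.tsv",
            "drug_id\tsmiles\ttargets\naspirin\tCC(=O)Oc1ccccc1C(=O)O\tPTGS1;PTGS2\n",
        )
        (rec,) = dataio.read_drug_library(p)
        assert rec.targets == {"PTGS1", "PTGS2"}
        assert rec.smiles is not None

    def test_bad_smiles_kept_without_structure(self, tmp_path):
        p = write(
            tmp_path / "lib.tsv",
            "drug_id\tsmiles\ttargets\nmystery\tnot_a_molecule\tGENE1\n",
        )
        (rec,) = dataio.read_drug_library(p)
        assert rec.smiles is None and rec.targets == {"GENE1"}

    def test_duplicate_drug_id_rejected(self, tmp_path):
        p = write(
            tmp_path / "lib.tsv",
            "drug_id\tsmiles\ttargets\na\tCCO\tG1\na\tCCO\tG2\n",
        )
        with pytest.raises(ValueError, match="duplicate drug_id"):
            dataio.read_drug_library(p)

    def test_library_round_trip_with_networks(self, tmp_path):
        net = GeneNetwork.from_edges([("G1", "G2", 0.5)])
        drugs = [
            dataio.DrugRecord("a", "CCO", {"G1"}, net),
            dataio.DrugRecord("b", None, set(), None),
        ]
        dataio.write_drug_library(drugs, tmp_path / "lib.tsv")
        back = dataio.read_drug_library(tmp_path / "lib.tsv")
        assert [d.drug_id for d in back] == ["a", "b"]
        assert back[0].perturbational_network == net
        assert back[1].smiles is None and back[1].perturbational_network is None


class TestMatrixIO:
    def test_write_has_labels_and_round_trips(self, tmp_path):
        m = DistanceMatrix(["b", "a"], np.array([[0.0, 1 / 3], [1 / 3, 0.0]]))
        dataio.write_matrix(m, tmp_path / "m.tsv")
        text = (tmp_path / "m.tsv").read_text()
        assert text.splitlines()[0] == "label\ta\tb"  # canonical order
        back = dataio.read_matrix(tmp_path / "m.tsv")
        assert back.labels == m.labels
        np.testing.assert_allclose(back.values, m.values, atol=1e-12, rtol=0)

    def test_float_round_trip_exact(self, tmp_path, rng):
        vals = rng.random((5, 5))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        m = DistanceMatrix([f"d{i}" for i in range(5)], vals)
        dataio.write_matrix(m, tmp_path / "m.tsv")
        assert dataio.read_matrix(tmp_path / "m.tsv") == m

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_network_round_trip(self, tmp_path):
        net = GeneNetwork.from_edges([("A", "B", 0.123456789012345), ("B", "C", 1.0)])
        dataio.write_network(net, tmp_path / "net.tsv", header_lines=["config: x=1"])
        assert dataio.read_network(tmp_path / "net.tsv") == net

    def test_front_round_trip(self, tmp_path):
        rows = [
            FrontEntry(("a", "b"), (2.0, 0.5, 0.25, 0.75, 1.5), 0, float("inf")),
            FrontEntry(("a", "c", "d"), (3.0, 0.1, 0.2, 0.3, 0.4), 0, 0.125),
        ]
        dataio.write_front(rows, tmp_path / "front.tsv")
        assert dataio.read_front(tmp_path / "front.tsv") == rows


def test_expression_round_trip(tmp_path, rng):
    ds = ExpressionDataset(
        ["g1", "g2"],
        ["s1", "s2", "s3", "s4"],
        rng.standard_normal((2, 4)),
        ["disease", "disease", "control", "control"],
    )
    dataio.write_expression(ds, tmp_path / "e.tsv", tmp_path / "a.tsv")
    back = dataio.read_expression(tmp_path / "e.tsv", tmp_path / "a.tsv")
    assert back.gene_ids == ds.gene_ids and back.condition == ds.condition
    np.testing.assert_allclose(back.values, ds.values, atol=1e-12, rtol=0)
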