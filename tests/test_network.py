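"""Network construction, differential comparison and serialization."""

import numpy as np
import networkx as nx
import pytest

from isoformnet.expression import IsoformExonMatrix
from isoformnet.annotation import ExonInterval
from isoformnet.model import IsoformNetwork, LDTIndependence
from isoformnet.network import (
    CoexpressionNetwork,
    Edge,
    IsoformNode,
    differential_network,
    infer_network,
    rank_edges,
    read_network_tsv,
    to_graphml,
    write_network_tsv,
)


def _node(g, i):
    return IsoformNode(g, i)


def _edge(a, b, p_value=0.01, T=3.0):
    return Edge(_node(*a), _node(*b), T=T, p_value=p_value)


def _matrix(gene, iso, values, samples=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    samples = samples or tuple(f"S{k}" for k in range(n))
    exons = tuple(ExonInterval("chr1", 1000 * (r + 1), 1000 * (r + 1) + 100) for r in range(p))
    return IsoformExonMatrix(iso, gene, exons, tuple(samples), values)


def _positive(X):
    return X - X.min() + 1.0


class TestInferNetwork:
    def test_planted_dependence_found_independents_not(self, rng):
        Z = rng.standard_normal((5, 100))
        m = [
            _matrix("G1", "I1", _positive(Z + 0.6 * Z)),
            _matrix("G2", "I1", _positive(rng.standard_normal((5, 100)) + 0.6 * Z)),
            _matrix("G3", "I1", _positive(rng.standard_normal((5, 100)))),
        ]
        net = infer_network(m, alpha=0.05)
        keys = {(str(e.node_a), str(e.node_b)) for e in net.edges}
        assert ("G1:I1", "G2:I1") in keys

    def test_intragene_pairs_excluded_by_default(self, rng):
        Z = _positive(rng.standard_normal((4, 60)))
        m = [_matrix("G1", "I1", Z), _matrix("G1", "I2", Z + 0.01)]
        net = infer_network(m, alpha=0.05)
        assert net.edges == []
        net2 = infer_network(m, alpha=0.05, include_intragene=True)
        assert len(net2.edges) == 1

    def test_edge_count_monotone_in_alpha(self, rng):
        mats = [
            _matrix(f"G{k}", "I1", _positive(rng.standard_normal((3, 50)))) for k in range(8)
        ]
        n_loose = len(infer_network(mats, alpha=0.2).edges)
        n_strict = len(infer_network(mats, alpha=0.01).edges)
        assert n_strict <= n_loose

    def test_sample_axis_mismatch_rejected(self, rng):
        a = _matrix("G1", "I1", _positive(rng.standard_normal((2, 30))))
        b = _matrix("G2", "I1", _positive(rng.standard_normal((2, 30))),
                    samples=tuple(f"T{k}" for k in range(30)))
        with pytest.raises(ValueError, match="sample axis"):
            infer_network([a, b])

    def test_undirected_input_order_invariance(self, rng):
        mats = [
            _matrix(f"G{k}", "I1", _positive(rng.standard_normal((3, 60)))) for k in range(5)
        ]
        net_fwd = infer_network(mats, alpha=0.2)
        net_rev = infer_network(list(reversed(mats)), alpha=0.2)
        assert net_fwd.edge_keys() == net_rev.edge_keys()

    def test_dimension_violating_pairs_skipped_not_fatal(self, rng):
        big = _matrix("G1", "I1", _positive(rng.standard_normal((25, 20))))
        small = _matrix("G2", "I1", _positive(rng.standard_normal((3, 20))))
        other = _matrix("G3", "I1", _positive(rng.standard_normal((3, 20))))
        net = infer_network([big, small, other], alpha=0.05)
        assert net.provenance["n_pairs_skipped"] == 2  # both pairs involving the 25-exon block


class TestDifferentialNetwork:
    def test_worked_toy_example(self):
        """Normal {I11-I21, I11-I23, I12-I23} vs cancer {I11-I21, I11-I22,
        I12-I23}: the differential network is lost {I11-I23}, gained {I11-I22}."""
        nodes = [_node("G1", f"I1{k}") for k in (1, 2)] + [
            _node("G2", f"I2{k}") for k in (1, 2, 3)
        ]
        normal = CoexpressionNetwork(
            "normal",
            nodes,
            [
                _edge(("G1", "I11"), ("G2", "I21")),
                _edge(("G1", "I11"), ("G2", "I23")),
                _edge(("G1", "I12"), ("G2", "I23")),
            ],
            alpha=0.05,
        )
        cancer = CoexpressionNetwork(
            "cancer",
            nodes,
            [
                _edge(("G1", "I11"), ("G2", "I21")),
                _edge(("G1", "I11"), ("G2", "I22")),
                _edge(("G1", "I12"), ("G2", "I23")),
            ],
            alpha=0.05,
        )
        diff = differential_network(normal, cancer)
        assert [(str(e.node_a), str(e.node_b)) for e in diff.lost_edges] == [
            ("G1:I11", "G2:I23")
        ]
        assert [(str(e.node_a), str(e.node_b)) for e in diff.gained_edges] == [
            ("G1:I11", "G2:I22")
        ]
        assert {e.key for e in diff.common_edges} == {
            (_node("G1", "I11"), _node("G2", "I21")),
            (_node("G1", "I12"), _node("G2", "I23")),
        }

    def test_self_difference_empty(self):
        nodes = [_node("G1", "I1"), _node("G2", "I1")]
        net = CoexpressionNetwork("n", nodes, [_edge(("G1", "I1"), ("G2", "I1"))], 0.05)
        diff = differential_network(net, net)
        assert diff.lost_edges == [] and diff.gained_edges == []
        assert len(diff.common_edges) == 1

    def test_disjoint_edge_sets(self):
        nodes = [_node("G1", "I1"), _node("G2", "I1"), _node("G3", "I1")]
        a = CoexpressionNetwork("n", nodes, [_edge(("G1", "I1"), ("G2", "I1"))], 0.05)
        b = CoexpressionNetwork("d", nodes, [_edge(("G1", "I1"), ("G3", "I1"))], 0.05)
        diff = differential_network(a, b)
        assert len(diff.lost_edges) == 1 and len(diff.gained_edges) == 1
        assert diff.common_edges == []

    def test_symmetric_difference_partition(self):
        nodes = [_node(f"G{k}", "I1") for k in range(5)]
        a = CoexpressionNetwork(
            "n", nodes,
            [_edge(("G0", "I1"), ("G1", "I1")), _edge(("G0", "I1"), ("G2", "I1"))], 0.05,
        )
        b = CoexpressionNetwork(
            "d", nodes,
            [_edge(("G0", "I1"), ("G2", "I1")), _edge(("G3", "I1"), ("G4", "I1"))], 0.05,
        )
        diff = differential_network(a, b)
        sym = {e.key for e in diff.lost_edges} | {e.key for e in diff.gained_edges}
        assert sym == a.edge_keys() ^ b.edge_keys()

    def test_mismatched_alpha_rejected(self):
        nodes = [_node("G1", "I1"), _node("G2", "I1")]
        a = CoexpressionNetwork("n", nodes, [], alpha=0.05)
        b = CoexpressionNetwork("d", nodes, [], alpha=0.01)
        with pytest.raises(ValueError, match="alpha"):
            differential_network(a, b)

    def test_untestable_isoform_annotated(self):
        na = [_node("G1", "I1"), _node("G2", "I1")]
        nb = [_node("G1", "I1")]  # G2:I1 untestable in disease
        a = CoexpressionNetwork("normal", na, [_edge(("G1", "I1"), ("G2", "I1"))], 0.05)
        b = CoexpressionNetwork("disease", nb, [], 0.05)
        diff = differential_network(a, b)
        key = diff.lost_edges[0].key
        assert diff.annotations[key] == "untestable-in-disease"


class TestRankingAndEdges:
    def test_rank_by_pvalue_then_canonical_order(self):
        e1 = _edge(("G2", "I1"), ("G3", "I1"), p_value=0.01)
        e2 = _edge(("G1", "I1"), ("G9", "I1"), p_value=0.01)
        e3 = _edge(("G1", "I1"), ("G2", "I1"), p_value=0.001)
        ranked = rank_edges([e1, e2, e3])
        assert ranked == [e3, e2, e1]
        assert rank_edges([]) == []

    def test_edge_canonicalization_and_weight(self):
        e = Edge(_node("G2", "I1"), _node("G1", "I1"), T=2.0, p_value=0.02)
        assert (e.node_a.gene_symbol, e.node_b.gene_symbol) == ("G1", "G2")
        assert e.weight == pytest.approx(0.98)
        with pytest.raises(ValueError, match="self-edge"):
            Edge(_node("G1", "I1"), _node("G1", "I1"), T=0, p_value=1)


class TestSerialization:
    def _net(self):
        nodes = [_node("G1", "I1"), _node("G2", "I1"), _node("G2", "I2")]
        edges = [
            _edge(("G1", "I1"), ("G2", "I1"), p_value=0.004, T=2.65),
            _edge(("G1", "I1"), ("G2", "I2"), p_value=0.04, T=1.75),
        ]
        return CoexpressionNetwork("normal", nodes, edges, alpha=0.05)

    def test_tsv_roundtrip(self, tmp_path):
        net = self._net()
        path = tmp_path / "net.tsv"
        write_network_tsv(net, str(path))
        back = read_network_tsv(str(path))
        assert back.condition_label == "normal" and back.alpha == 0.05
        assert back.edge_keys() == net.edge_keys()
        assert sorted(back.nodes) == sorted(net.nodes)

    def test_graphml_export(self, tmp_path):
        net = self._net()
        path = tmp_path / "net.graphml"
        to_graphml(net, str(path))
        g = nx.read_graphml(str(path))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        _, _, attrs = next(iter(g.edges(data=True)))
        assert {"T", "p_value", "weight", "status"} <= set(attrs)


class TestModelSurface:
    def test_pair_model_summary(self, rng):
        Z = rng.standard_normal((4, 80))
        res = LDTIndependence(Z + 0.5 * Z, rng.standard_normal((4, 80)) + 0.5 * Z).fit()
        text = res.summary()
        assert "LDT independence test" in text and "p-value" in text
        assert res.edge  # strongly dependent blocks

    def test_network_model_fit_and_diff(self, rng):
        Z = rng.standard_normal((5, 100))
        mats = [
            _matrix("G1", "I1", _positive(Z + 0.6 * Z)),
            _matrix("G2", "I1", _positive(rng.standard_normal((5, 100)) + 0.6 * Z)),
            _matrix("G3", "I1", _positive(rng.standard_normal((5, 100)))),
        ]
        res_n = IsoformNetwork(mats, "normal").fit(alpha=0.01)
        res_d = IsoformNetwork(mats, "disease").fit(alpha=0.01)
        frame = res_n.to_frame()
        assert {"gene_a", "p_value", "weight"} <= set(frame.columns)
        diff = res_n.differential(res_d)
        assert diff.lost_edges == [] and diff.gained_edges == []
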