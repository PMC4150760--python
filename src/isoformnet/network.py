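"""Isoform-level co-expression networks and differential (rewiring) networks.

A network is inferred per condition (e.g. normal, tumor) by applying the LDT
independence test to every unordered pair of isoform exon-matrices from
distinct genes (optionally also within genes, which probes isoform-mediated
auto-regulation).  Edges are undirected, weighted by 1 - p_value for display,
and ranked by raw p-value.  The differential network between two conditions
is the symmetric difference of the edge sets: edges lost in disease (present
only in normal) and gained in disease (present only in disease), with common
edges kept for audit.  Edges incident to an isoform that was untestable in
one condition (filtered out there) are annotated so that loss/gain is not
over-read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import IsoformExonMatrix
from .ldt import ldt_test

logger = logging.getLogger(__name__)

__all__ = [
    "IsoformNode",
    "Edge",
    "CoexpressionNetwork",
    "DifferentialNetwork",
    "infer_network",
    "differential_network",
    "rank_edges",
    "write_network_tsv",
    "read_network_tsv",
    "to_graphml",
]


@dataclass(frozen=True, order=True)
class IsoformNode:
    gene_symbol: str
    isoform_id: str

    def __str__(self) -> str:
        return f"{self.gene_symbol}:{self.isoform_id}"


@dataclass(frozen=True)
class Edge:
    """Undirected edge; endpoints stored in canonical (sorted) order."""

    node_a: IsoformNode
    node_b: IsoformNode
    T: float
    p_value: float

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise ValueError("self-edges are not allowed")
        if self.node_b < self.node_a:
            a, b = self.node_a, self.node_b
            object.__setattr__(self, "node_a", b)
            object.__setattr__(self, "node_b", a)

    @property
    def key(self) -> tuple[IsoformNode, IsoformNode]:
        return (self.node_a, self.node_b)

    @property
    def weight(self) -> float:
        """Display weight; ranking always uses the raw p-value."""
        return 1.0 - self.p_value


@dataclass
class CoexpressionNetwork:
    condition_label: str
    nodes: list[IsoformNode]
    edges: list[Edge]
    alpha: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        node_set = set(self.nodes)
        keys = set()
        for e in self.edges:
            if e.node_a not in node_set or e.node_b not in node_set:
                raise ValueError(f"edge {e.key} references a node outside the network")
            if e.key in keys:
                raise ValueError(f"duplicate edge {e.key}")
            keys.add(e.key)

    def edge_keys(self) -> set[tuple[IsoformNode, IsoformNode]]:
        return {e.key for e in self.edges}


@dataclass
class DifferentialNetwork:
    """Edges lost / gained in disease relative to normal; common for audit.

    ``annotations`` marks edges whose interpretation is weakened because an
    endpoint was untestable (filtered out) in the other condition.
    """

    lost_edges: list[Edge]
    gained_edges: list[Edge]
    common_edges: list[Edge]
    condition_a: str
    condition_b: str
    annotations: dict[tuple[IsoformNode, IsoformNode], str] = field(default_factory=dict)

    def __post_init__(self):
        lost = {e.key for e in self.lost_edges}
        gained = {e.key for e in self.gained_edges}
        common = {e.key for e in self.common_edges}
        if lost & gained or (lost | gained) & common:
            raise ValueError("lost/gained/common edge sets must be disjoint")


def infer_network(
    matrices: list[IsoformExonMatrix],
    alpha: float = 0.05,
    include_intragene: bool = False,
    condition_label: str = "condition",
    provenance: dict | None = None,
) -> CoexpressionNetwork:
    """Pairwise LDT testing over isoform matrices -> co-expression network.

    Every unordered pair of isoforms from distinct genes is tested (same-gene
    pairs too when ``include_intragene``); a pair whose dimensions violate
    n - 1 > max(p, q) is skipped and logged rather than silently dropped.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two isoform matrices to infer a network")
    sample_axis = matrices[0].sample_ids
    for m in matrices:
        if m.sample_ids != sample_axis:
            raise ValueError(f"isoform {m.isoform_id} has a different sample axis")
    mats = sorted(matrices, key=lambda m: (m.gene_symbol, m.isoform_id))
    nodes = [IsoformNode(m.gene_symbol, m.isoform_id) for m in mats]
    edges: list[Edge] = []
    n_skipped = 0
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            a, b = mats[i], mats[j]
            if a.gene_symbol == b.gene_symbol and not include_intragene:
                continue
            try:
                res = ldt_test(a.values, b.values, alpha=alpha)
            except (ValueError, np.linalg.LinAlgError) as exc:
                n_skipped += 1
                logger.warning(
                    "pair %s:%s vs %s:%s skipped (p=%d, q=%d, n=%d): %s",
                    a.gene_symbol, a.isoform_id, b.gene_symbol, b.isoform_id,
                    a.p, b.p, a.n, exc,
                )
                continue
            if res.edge:
                edges.append(
                    Edge(
                        IsoformNode(a.gene_symbol, a.isoform_id),
                        IsoformNode(b.gene_symbol, b.isoform_id),
                        T=res.T,
                        p_value=res.p_value,
                    )
                )
    prov = dict(provenance or {})
    prov.setdefault("alpha", alpha)
    prov.setdefault("include_intragene", include_intragene)
    prov.setdefault("n_pairs_skipped", n_skipped)
    return CoexpressionNetwork(
        condition_label=condition_label, nodes=nodes, edges=edges, alpha=alpha, provenance=prov
    )


def differential_network(
    net_normal: CoexpressionNetwork, net_disease: CoexpressionNetwork
) -> DifferentialNetwork:
    """Graph comparison: drop common edges, keep what is lost/gained in disease."""
    if net_normal.alpha != net_disease.alpha:
        raise ValueError(
            f"networks built at different alpha ({net_normal.alpha} vs {net_disease.alpha}) "
            "are not comparable"
        )
    keys_n = net_normal.edge_keys()
    keys_d = net_disease.edge_keys()
    lost = sorted((e for e in net_normal.edges if e.key not in keys_d), key=lambda e: e.key)
    gained = sorted((e for e in net_disease.edges if e.key not in keys_n), key=lambda e: e.key)
    common = sorted((e for e in net_normal.edges if e.key in keys_d), key=lambda e: e.key)
    nodes_n = set(net_normal.nodes)
    nodes_d = set(net_disease.nodes)
    annotations: dict[tuple[IsoformNode, IsoformNode], str] = {}
    for e in lost:
        missing = [x for x in e.key if x not in nodes_d]
        if missing:
            annotations[e.key] = f"untestable-in-{net_disease.condition_label}"
    for e in gained:
        missing = [x for x in e.key if x not in nodes_n]
        if missing:
            annotations[e.key] = f"untestable-in-{net_normal.condition_label}"
    return DifferentialNetwork(
        lost_edges=lost,
        gained_edges=gained,
        common_edges=common,
        condition_a=net_normal.condition_label,
        condition_b=net_disease.condition_label,
        annotations=annotations,
    )


def rank_edges(edges: list[Edge]) -> list[Edge]:
    """Ascending p-value; ties broken by canonical node-pair order."""
    return sorted(edges, key=lambda e: (e.p_value, e.key))


def _edge_rows(edges: list[Edge], status: str, annotations: dict | None = None) -> list[dict]:
    annotations = annotations or {}
    return [
        {
            "gene_a": e.node_a.gene_symbol,
            "isoform_a": e.node_a.isoform_id,
            "gene_b": e.node_b.gene_symbol,
            "isoform_b": e.node_b.isoform_id,
            "T": e.T,
            "p_value": e.p_value,
            "status": status,
            "note": annotations.get(e.key, ""),
        }
        for e in edges
    ]


def write_network_tsv(obj: CoexpressionNetwork | DifferentialNetwork, path: str) -> None:
    """Edge-list TSV; differential networks carry a status column."""
    if isinstance(obj, CoexpressionNetwork):
        rows = _edge_rows(rank_edges(obj.edges), "common")
        header = f"# condition={obj.condition_label}\talpha={obj.alpha}\n"
        # every node appears even if isolated, as a nodes comment line
        header += "# nodes=" + ";".join(str(n) for n in obj.nodes) + "\n"
    else:
        rows = (
            _edge_rows(rank_edges(obj.lost_edges), "lost", obj.annotations)
            + _edge_rows(rank_edges(obj.gained_edges), "gained", obj.annotations)
            + _edge_rows(rank_edges(obj.common_edges), "common")
        )
        header = f"# differential\tnormal={obj.condition_a}\tdisease={obj.condition_b}\n"
    cols = ["gene_a", "isoform_a", "gene_b", "isoform_b", "T", "p_value", "status", "note"]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_network_tsv(path: str) -> CoexpressionNetwork:
    """Read a co-expression network TSV written by :func:`write_network_tsv`."""
    condition, alpha, nodes = "condition", 0.05, []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tokens in line[1:].strip().split("\t"):
                if tokens.startswith("condition="):
                    condition = tokens.split("=", 1)[1]
                elif tokens.startswith("alpha="):
                    alpha = float(tokens.split("=", 1)[1])
                elif tokens.startswith("nodes="):
                    for item in tokens.split("=", 1)[1].split(";"):
                        if item:
                            g, i = item.split(":", 1)
                            nodes.append(IsoformNode(g, i))
    df = pd.read_csv(path, sep="\t", comment="#")
    edges = [
        Edge(
            IsoformNode(r.gene_a, r.isoform_a),
            IsoformNode(r.gene_b, r.isoform_b),
            T=float(r.T),
            p_value=float(r.p_value),
        )
        for r in df.itertuples(index=False)
    ]
    if not nodes:
        nodes = sorted({n for e in edges for n in e.key})
    return CoexpressionNetwork(
        condition_label=condition, nodes=nodes, edges=edges, alpha=alpha
    )


def to_graphml(obj: CoexpressionNetwork | DifferentialNetwork, path: str) -> None:
    """GraphML export with T, p_value, weight and status edge attributes."""
    g = nx.Graph()
    if isinstance(obj, CoexpressionNetwork):
        groups = [(obj.edges, "common")]
        for node in obj.nodes:
            g.add_node(str(node), gene=node.gene_symbol, isoform=node.isoform_id)
    else:
        groups = [
            (obj.lost_edges, "lost"),
            (obj.gained_edges, "gained"),
            (obj.common_edges, "common"),
        ]
    for edges, status in groups:
        for e in edges:
            g.add_edge(
                str(e.node_a),
                str(e.node_b),
                T=e.T,
                p_value=e.p_value,
                weight=e.weight,
                status=status,
            )
    nx.write_graphml(g, path)
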