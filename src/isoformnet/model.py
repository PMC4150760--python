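"""Model/Results objects wrapping the LDT test and network inference.

``LDTIndependence`` treats a pair of exon-expression blocks as the data of a
model whose ``fit`` performs the trace-based independence test and returns a
results object carrying the statistic, its asymptotic null moments, the
p-value and a ``summary()`` table.  ``IsoformNetwork`` does the same at the
network level: the data are a set of corrected isoform exon-matrices over a
common sample axis, ``fit`` runs all pairwise tests, and the results expose
the edge table, a summary, and a ``differential`` comparison against another
fitted condition.  The functional interface (``ldt_test``, ``infer_network``,
``differential_network``) remains available for script use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import IsoformExonMatrix
from .ldt import LdtResult, ldt_test
from .network import (
    CoexpressionNetwork,
    DifferentialNetwork,
    differential_network,
    infer_network,
    rank_edges,
)

__all__ = [
    "LDTIndependence",
    "LDTIndependenceResults",
    "IsoformNetwork",
    "IsoformNetworkResults",
]


class LDTIndependence:
    """Independence model for a pair of exon blocks over shared samples."""

    def __init__(self, X1: np.ndarray, X2: np.ndarray):
        self.X1 = np.atleast_2d(np.asarray(X1, dtype=float))
        self.X2 = np.atleast_2d(np.asarray(X2, dtype=float))

    @classmethod
    def from_matrices(cls, m1: IsoformExonMatrix, m2: IsoformExonMatrix) -> "LDTIndependence":
        if m1.sample_ids != m2.sample_ids:
            raise ValueError("the two isoform matrices have different sample axes")
        obj = cls(m1.values, m2.values)
        obj.labels = (f"{m1.gene_symbol}:{m1.isoform_id}", f"{m2.gene_symbol}:{m2.isoform_id}")
        return obj

    def fit(self, alpha: float = 0.05) -> "LDTIndependenceResults":
        return LDTIndependenceResults(self, ldt_test(self.X1, self.X2, alpha=alpha))


class LDTIndependenceResults:
    """Fitted LDT test; attribute access mirrors the underlying result record."""

    def __init__(self, model: LDTIndependence, result: LdtResult):
        self.model = model
        self.result = result

    def __getattr__(self, name):
        return getattr(self.result, name)

    def summary(self) -> str:
        r = self.result
        lines = [
            "LDT independence test (H0: blocks independent)",
            "=" * 46,
            f"dimensions        p = {r.p}, q = {r.q}, n = {r.n}",
            f"trace statistic   L_n = {r.L_n:.6f}",
            f"asymptotic null   E = {r.E_asym:.6f}, V = {r.V_asym:.6g}",
            f"standardized      T = {r.T:.4f}",
            f"p-value           {r.p_value:.4g}",
            f"decision          {'edge' if r.edge else 'no edge'} "
            f"(alpha = {r.alpha}, Z_alpha = {r.critical_value:.4f})",
        ]
        return "\n".join(lines)


class IsoformNetwork:
    """Co-expression network model over a set of isoform exon-matrices."""

    def __init__(self, matrices: list[IsoformExonMatrix], condition_label: str = "condition"):
        self.matrices = list(matrices)
        self.condition_label = condition_label

    def fit(
        self, alpha: float = 0.05, include_intragene: bool = False
    ) -> "IsoformNetworkResults":
        net = infer_network(
            self.matrices,
            alpha=alpha,
            include_intragene=include_intragene,
            condition_label=self.condition_label,
        )
        return IsoformNetworkResults(self, net)


class IsoformNetworkResults:
    def __init__(self, model: IsoformNetwork, network: CoexpressionNetwork):
        self.model = model
        self.network = network

    @property
    def edges(self):
        return self.network.edges

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": e.node_a.gene_symbol,
                "isoform_a": e.node_a.isoform_id,
                "gene_b": e.node_b.gene_symbol,
                "isoform_b": e.node_b.isoform_id,
                "T": e.T,
                "p_value": e.p_value,
                "weight": e.weight,
            }
            for e in rank_edges(self.network.edges)
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_a", "isoform_a", "gene_b", "isoform_b", "T", "p_value", "weight"],
        )

    def differential(self, disease: "IsoformNetworkResults") -> DifferentialNetwork:
        """Differential network with self as normal and ``disease`` as disease."""
        return differential_network(self.network, disease.network)

    def summary(self) -> str:
        net = self.network
        lines = [
            f"Isoform co-expression network [{net.condition_label}]",
            "=" * 48,
            f"nodes  {len(net.nodes)}    edges  {len(net.edges)}    alpha  {net.alpha}",
        ]
        frame = self.to_frame()
        if len(frame):
            lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
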