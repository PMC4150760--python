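"""Exon- and isoform-level expression tables and the corrected exon matrix.

The multivariate variable tested for co-expression is, per isoform, a p x n
matrix of exon expression values (p exons, n samples).  Raw exon values come
from a level-3-style table keyed by genomic interval; because an exon may be
carried by several isoforms, each instance is rescaled by the relative
abundance of its owning isoform in that sample:

    Cex[m, n, p] = E[m, n, p] * W[m, n, p],
    W[m, n, p]   = I[m, n] / sum_{i in sharing isoforms} I[i, n],

where ``I`` is the isoform-expression table.  Exons expressed in fewer than
half of the samples (configurable) are discarded: inference with most of the
data missing is unreliable.  "Expressed" means a strictly positive,
non-missing corrected value; a zero total abundance at a shared exon makes
the relative weight undefined, so the value is flagged missing rather than
invented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import (
    DEFAULT_TOLERANCE_NT,
    ExonInterval,
    IsoformModel,
    SharedExonTable,
    match_exon_boundaries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTables",
    "IsoformExonMatrix",
    "read_exon_expression",
    "read_isoform_expression",
    "filter_expressed_exons",
    "correction_weight",
    "build_isoform_matrix",
    "write_isoform_matrices",
    "read_isoform_matrices",
    "DEFAULT_MIN_FRACTION",
]

DEFAULT_MIN_FRACTION = 0.5

_EXON_INDEX_COLS = ["chrom", "start", "end", "strand"]


@dataclass
class ExpressionTables:
    """Paired raw exon and isoform expression tables over one sample set.

    ``exon_expr``: wide DataFrame, rows indexed by (chrom, start, end, strand),
    one column per sample, NaN = missing.  ``isoform_expr``: wide DataFrame,
    rows indexed by isoform_id, same sample columns.
    """

    exon_expr: pd.DataFrame
    isoform_expr: pd.DataFrame

    def __post_init__(self):
        ex = set(self.exon_expr.columns)
        iso = set(self.isoform_expr.columns)
        if ex != iso:
            raise ValueError(
                f"exon and isoform tables disagree on samples: "
                f"{sorted(ex ^ iso)} present in only one table"
            )
        if (self.exon_expr.to_numpy() < 0).any() or (self.isoform_expr.to_numpy() < 0).any():
            raise ValueError("expression values must be >= 0 (or missing)")
        # one ordered sample universe
        self.isoform_expr = self.isoform_expr[list(self.exon_expr.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.exon_expr.columns)

    def exon_rows(self) -> list[ExonInterval]:
        return [ExonInterval(c, int(s), int(e), st) for c, s, e, st in self.exon_expr.index]


@dataclass(frozen=True)
class IsoformExonMatrix:
    """Corrected exon-expression matrix (p exons x n samples) for one isoform."""

    isoform_id: str
    gene_symbol: str
    exon_keys: tuple[ExonInterval, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.exon_keys), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.exon_keys)} exons x {len(self.sample_ids)} samples"
            )
        if len(self.exon_keys) < 1:
            raise ValueError("matrix must retain at least one exon")
        if np.nanmin(self.values) < 0:
            raise ValueError("corrected expression values must be >= 0")

    @property
    def p(self) -> int:
        return len(self.exon_keys)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def read_exon_expression(path: str) -> pd.DataFrame:
    """Read an exon-expression TSV (long or wide dialect, auto-detected).

    Long: header ``sample_id  chrom  start  end  strand  value``.
    Wide: header ``chrom  start  end  strand  <sample> ...``.
    Returns the wide form indexed by (chrom, start, end, strand).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if cols[:6] == ["sample_id", "chrom", "start", "end", "strand", "value"]:
        wide = df.pivot_table(
            index=_EXON_INDEX_COLS, columns="sample_id", values="value", aggfunc="first"
        )
        wide.columns = [str(c) for c in wide.columns]
        return wide
    if cols[:4] == _EXON_INDEX_COLS:
        wide = df.set_index(_EXON_INDEX_COLS)
        wide.columns = [str(c) for c in wide.columns]
        return wide
    raise ValueError(f"{path}: unrecognized exon-expression header {cols[:6]}")


def read_isoform_expression(path: str) -> pd.DataFrame:
    """Read an isoform-expression TSV (``sample_id  isoform_id  value``)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["sample_id", "isoform_id", "value"]
    if list(df.columns)[:3] != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)[:3]}")
    wide = df.pivot_table(index="isoform_id", columns="sample_id", values="value", aggfunc="first")
    wide.columns = [str(c) for c in wide.columns]
    return wide


def filter_expressed_exons(
    matrix_rows: np.ndarray, min_fraction: float = DEFAULT_MIN_FRACTION
) -> list[int]:
    """Indices of exon rows expressed in at least ``min_fraction`` of samples.

    Expressed = strictly positive and non-missing.  The threshold is
    inclusive: with 10 samples and min_fraction 0.5, 5 expressed samples keep
    the exon.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    rows = np.asarray(matrix_rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("matrix_rows must be 2-D (exons x samples)")
    expressed = (rows > 0) & ~np.isnan(rows)
    frac = expressed.mean(axis=1)
    kept = [int(i) for i in np.flatnonzero(frac >= min_fraction)]
    if not kept:
        logger.warning("no exon passed the %.0f%% expressed filter", 100 * min_fraction)
    return kept


def correction_weight(
    isoform_id: str,
    sample_id: str,
    exon_key: ExonInterval,
    shared: SharedExonTable,
    isoform_expr: pd.DataFrame,
) -> tuple[float, bool]:
    """Relative-abundance weight W = I[m,n] / sum of sharing isoforms' I[.,n].

    Returns ``(weight, missing)``.  Weight is 1 when the exon is private to
    the isoform; when the total abundance across sharing isoforms is zero the
    relative abundance is undefined and the value is flagged missing
    (weight 0).
    """
    if isoform_id not in isoform_expr.index:
        raise KeyError(f"isoform {isoform_id!r} absent from the isoform-expression table")
    sharing = shared.sharing_isoforms(exon_key)
    if not sharing:
        raise KeyError(f"exon {exon_key} not present in the shared-exon table")
    ids = [iso for _, iso in sharing]
    if len(ids) == 1:
        return 1.0, False
    abundances = []
    for iso in ids:
        if iso not in isoform_expr.index:
            raise KeyError(f"isoform {iso!r} (sharing exon {exon_key}) absent from table")
        v = isoform_expr.at[iso, sample_id]
        abundances.append(0.0 if pd.isna(v) else float(v))
    total = sum(abundances)
    if total == 0.0:
        return 0.0, True
    own = isoform_expr.at[isoform_id, sample_id]
    own = 0.0 if pd.isna(own) else float(own)
    return own / total, False


def build_isoform_matrix(
    isoform: IsoformModel,
    tables: ExpressionTables,
    shared: SharedExonTable,
    tolerance_nt: int = DEFAULT_TOLERANCE_NT,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> IsoformExonMatrix | None:
    """Corrected exon matrix for one isoform, or None if nothing survives.

    Pipeline: match annotated exon boundaries to expression rows (±tolerance),
    extract raw values, rescale each (exon, sample) cell by the isoform's
    relative abundance, then drop exons expressed in fewer than
    ``min_fraction`` of samples.  Missing cells within retained exons are set
    to 0 (logged); they carry no expression evidence.
    """
    rows = tables.exon_rows()
    mapping = match_exon_boundaries(isoform, rows, tolerance_nt)
    if not mapping:
        return None
    samples = tables.samples
    matched = sorted(mapping)
    raw = np.empty((len(matched), len(samples)))
    corrected = np.empty_like(raw)
    for out_i, exon_i in enumerate(matched):
        row = mapping[exon_i]
        raw[out_i] = tables.exon_expr.loc[(row.chrom, row.start, row.end, row.strand)].to_numpy(
            dtype=float
        )
        for s_i, sample in enumerate(samples):
            w, missing = correction_weight(
                isoform.isoform_id, sample, isoform.exons[exon_i], shared, tables.isoform_expr
            )
            if missing or np.isnan(raw[out_i, s_i]):
                corrected[out_i, s_i] = np.nan
            else:
                corrected[out_i, s_i] = raw[out_i, s_i] * w
    kept = filter_expressed_exons(corrected, min_fraction)
    if not kept:
        logger.warning(
            "isoform %s (%s): no exon passed the expressed filter; untestable",
            isoform.isoform_id,
            isoform.gene_symbol,
        )
        return None
    values = corrected[kept]
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info(
            "isoform %s: %d missing value(s) in retained exons set to 0",
            isoform.isoform_id,
            n_missing,
        )
        values = np.nan_to_num(values, nan=0.0)
    exon_keys = tuple(isoform.exons[i] for i in (matched[k] for k in kept))
    return IsoformExonMatrix(
        isoform_id=isoform.isoform_id,
        gene_symbol=isoform.gene_symbol,
        exon_keys=exon_keys,
        sample_ids=tuple(samples),
        values=values,
    )


def build_condition_matrices(
    annotation_path: str,
    exon_expr_path: str,
    isoform_expr_path: str,
    gene_list: list[str],
    tolerance_nt: int = DEFAULT_TOLERANCE_NT,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> list[IsoformExonMatrix]:
    """File-level pipeline: annotation + expression tables -> corrected matrices.

    The expressed-exon filter is applied within this dataset only, so networks
    for different conditions are built from independently filtered matrices.
    """
    from .annotation import build_shared_exon_table, parse_annotation

    models = parse_annotation(annotation_path, gene_list)
    shared = build_shared_exon_table(models, tolerance_nt)
    tables = ExpressionTables(
        exon_expr=read_exon_expression(exon_expr_path),
        isoform_expr=read_isoform_expression(isoform_expr_path),
    )
    out = []
    for model in models:
        m = build_isoform_matrix(model, tables, shared, tolerance_nt, min_fraction)
        if m is not None:
            out.append(m)
    return out


def write_isoform_matrices(matrices: list[IsoformExonMatrix], path: str) -> None:
    """Serialize corrected matrices to a single wide TSV (round-trippable)."""
    frames = []
    for m in matrices:
        df = pd.DataFrame(m.values, columns=list(m.sample_ids))
        df.insert(0, "gene_symbol", m.gene_symbol)
        df.insert(1, "isoform_id", m.isoform_id)
        df.insert(2, "chrom", [e.chrom for e in m.exon_keys])
        df.insert(3, "start", [e.start for e in m.exon_keys])
        df.insert(4, "end", [e.end for e in m.exon_keys])
        df.insert(5, "strand", [e.strand for e in m.exon_keys])
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_isoform_matrices(path: str) -> list[IsoformExonMatrix]:
    """Inverse of :func:`write_isoform_matrices`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = ["gene_symbol", "isoform_id", "chrom", "start", "end", "strand"]
    samples = [c for c in df.columns if c not in meta]
    out = []
    for (gene, iso), grp in df.groupby(["gene_symbol", "isoform_id"], sort=True):
        exons = tuple(
            ExonInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in grp.itertuples(index=False)
        )
        out.append(
            IsoformExonMatrix(
                isoform_id=iso,
                gene_symbol=gene,
                exon_keys=exons,
                sample_ids=tuple(samples),
                values=grp[samples].to_numpy(dtype=float),
            )
        )
    return out
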