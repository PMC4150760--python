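"""Transcript annotation parsing and shared-exon bookkeeping.

Gene models arrive either as GTF (1-based inclusive coordinates, parsed with
gffutils) or as a refFlat-style TSV (0-based half-open, parsed with pandas).
Internally every interval is 0-based half-open.  Because mammalian isoforms of
a gene frequently share exons, the isoforms of all genes of interest are
scanned for exon boundaries that coincide within a small tolerance (sequencing
and annotation jitter, default ±5 nt) and summarized into a shared-exon table:
one canonical key per distinct exon, listing every (gene, isoform) instance
that carries it.  That table drives the relative-abundance correction applied
when exon expression is split among the isoforms sharing the exon.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExonInterval",
    "IsoformModel",
    "SharedExonTable",
    "parse_annotation",
    "build_shared_exon_table",
    "match_exon_boundaries",
    "DEFAULT_TOLERANCE_NT",
]

DEFAULT_TOLERANCE_NT = 5


@dataclass(frozen=True, order=True)
class ExonInterval:
    """Genomic exon interval, 0-based half-open; strand '+', '-' or '.'."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")


@dataclass(frozen=True)
class IsoformModel:
    """One transcript: ordered, non-overlapping exons of a gene's isoform."""

    isoform_id: str
    gene_symbol: str
    exons: tuple[ExonInterval, ...]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"isoform {self.isoform_id} has no exons")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"isoform {self.isoform_id}: exons not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end and a.chrom == b.chrom:
                raise ValueError(
                    f"isoform {self.isoform_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def _strands_compatible(a: str, b: str) -> bool:
    # strand constrains matching only when known on both sides
    return a == "." or b == "." or a == b


def _boundaries_match(a: ExonInterval, b: ExonInterval, tol: int) -> bool:
    return (
        a.chrom == b.chrom
        and abs(a.start - b.start) <= tol
        and abs(a.end - b.end) <= tol
        and _strands_compatible(a.strand, b.strand)
    )


@dataclass
class SharedExonTable:
    """Canonical exon key -> list of (gene_symbol, isoform_id) instances.

    Keys are the boundaries of the first-seen instance; a later exon joins an
    existing key when chrom matches, both boundary offsets are within the
    tolerance, and strands do not conflict.
    """

    tolerance_nt: int = DEFAULT_TOLERANCE_NT
    entries: dict[ExonInterval, list[tuple[str, str]]] = field(default_factory=dict)

    def canonical_key(self, exon: ExonInterval) -> ExonInterval | None:
        """Return the table key this exon collapses onto, or None."""
        # exact hit first, then tolerance scan (tables here are small)
        if exon in self.entries:
            return exon
        for key in self.entries:
            if _boundaries_match(key, exon, self.tolerance_nt):
                return key
        return None

    def sharing_isoforms(self, exon: ExonInterval) -> list[tuple[str, str]]:
        key = self.canonical_key(exon)
        return list(self.entries[key]) if key is not None else []

    def add(self, exon: ExonInterval, gene_symbol: str, isoform_id: str) -> ExonInterval:
        key = self.canonical_key(exon)
        if key is None:
            key = exon
            self.entries[key] = []
        inst = (gene_symbol, isoform_id)
        if inst not in self.entries[key]:
            self.entries[key].append(inst)
        return key

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": k.chrom,
                "start": k.start,
                "end": k.end,
                "strand": k.strand,
                "instances": ";".join(f"{g}:{i}" for g, i in v),
            }
            for k, v in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "instances"])


def build_shared_exon_table(
    models: list[IsoformModel], tolerance_nt: int = DEFAULT_TOLERANCE_NT
) -> SharedExonTable:
    """Collapse the exons of all isoform models into a shared-exon table."""
    if tolerance_nt < 0:
        raise ValueError("tolerance_nt must be >= 0")
    table = SharedExonTable(tolerance_nt=tolerance_nt)
    for model in models:
        for exon in model.exons:
            table.add(exon, model.gene_symbol, model.isoform_id)
    return table


def match_exon_boundaries(
    isoform: IsoformModel,
    exon_expr_rows: list[ExonInterval],
    tolerance_nt: int = DEFAULT_TOLERANCE_NT,
) -> dict[int, ExonInterval]:
    """Map each annotated exon to the best-matching expression-table row.

    A row qualifies when chrom matches and both boundary offsets are within
    the tolerance; among several candidates the smallest |dstart| + |dend|
    wins, ties broken by the smaller row start.  Unmatched exons are absent
    from the returned mapping.
    """
    if tolerance_nt < 0:
        raise ValueError("tolerance_nt must be >= 0")
    mapping: dict[int, ExonInterval] = {}
    for idx, exon in enumerate(isoform.exons):
        best = None
        best_score = None
        for row in exon_expr_rows:
            if not _boundaries_match(exon, row, tolerance_nt):
                continue
            score = (abs(exon.start - row.start) + abs(exon.end - row.end), row.start)
            if best_score is None or score < best_score:
                best, best_score = row, score
        if best is not None:
            mapping[idx] = best
    if not mapping:
        logger.warning(
            "isoform %s (%s): no exon matched any expression row within ±%d nt",
            isoform.isoform_id,
            isoform.gene_symbol,
            tolerance_nt,
        )
    return mapping


def _parse_refflat(path: str, wanted: set[str]) -> list[IsoformModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["geneName", "name", "chrom", "strand", "exonStarts", "exonEnds"],
        dtype=str,
    )
    models = []
    for rec in df.itertuples(index=False):
        if rec.geneName not in wanted:
            continue
        starts = [int(s) for s in str(rec.exonStarts).rstrip(",").split(",")]
        ends = [int(s) for s in str(rec.exonEnds).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise ValueError(f"{path}: exonStarts/exonEnds length mismatch for {rec.name}")
        exons = tuple(
            sorted(
                (ExonInterval(rec.chrom, s, e, rec.strand) for s, e in zip(starts, ends)),
                key=lambda x: x.start,
            )
        )
        models.append(IsoformModel(rec.name, rec.geneName, exons))
    return models


def _parse_gtf(path: str, wanted: set[str]) -> list[IsoformModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [None])[0]
        tx = (feat.attributes.get("transcript_id") or [None])[0]
        if gene is None or tx is None or gene not in wanted:
            continue
        rec = by_tx.setdefault(tx, {"gene": gene, "exons": []})
        # GTF is 1-based inclusive; convert to 0-based half-open
        rec["exons"].append(
            ExonInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        )
    models = []
    for tx, rec in by_tx.items():
        exons = tuple(sorted(rec["exons"], key=lambda x: x.start))
        models.append(IsoformModel(tx, rec["gene"], exons))
    return models


def parse_annotation(annotation_file: str, gene_list: list[str]) -> list[IsoformModel]:
    """Parse a GTF or refFlat-style annotation into isoform models.

    Only genes in ``gene_list`` are returned; output is sorted by
    (gene_symbol, isoform_id).  Genes with no isoform in the file produce a
    logged warning and are omitted.
    """
    if not gene_list:
        raise ValueError("gene_list must be non-empty")
    if not os.path.exists(annotation_file):
        raise FileNotFoundError(annotation_file)
    wanted = set(gene_list)
    ext = os.path.splitext(annotation_file)[1].lower()
    if ext in (".gtf", ".gff", ".gff3"):
        models = _parse_gtf(annotation_file, wanted)
    elif ext in (".txt", ".tsv", ".refflat", ".bed"):
        models = _parse_refflat(annotation_file, wanted)
    else:
        raise ValueError(
            f"unrecognized annotation dialect for {annotation_file!r}; "
            "expected .gtf/.gff or a refFlat-style .tsv/.txt"
        )
    found = {m.gene_symbol for m in models}
    for gene in sorted(wanted - found):
        logger.warning("gene %s: no isoforms found in %s; omitted", gene, annotation_file)
    return sorted(models, key=lambda m: (m.gene_symbol, m.isoform_id))
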