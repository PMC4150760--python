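"""Synthetic fixture generator emulating level-3-style exon RNA-Seq inputs.

Writes, for a "normal" and a "disease" condition, the three file kinds the
pipeline consumes — a transcript annotation, a per-sample exon-expression
table and a per-sample isoform-expression table — with a known ground truth:

* two multi-isoform genes with private (unshared) exons carry planted
  co-expression edges that differ between conditions (a lost and a gained
  edge), so the full pipeline's differential network can be checked;
* additional genes whose isoforms share exons exercise the
  relative-abundance correction (the manifest records raw values and
  abundances so corrected matrices can be recomputed independently).

Planted dependence between two isoforms adds a per-edge latent factor to
both exon blocks with loading sqrt(c0*(1+c0)), reproducing the per-exon
cross-block covariance c0*(1+c0) of the two-block Monte-Carlo design; at the
default c0 = 0.6 and 100 samples the detection power of the LDT test is
essentially 1.  Latent Gaussian signals are mapped to expression space by a
positive affine transform (baseline 50, scale 5, clipped at 0 — clipping is
a > 9-sigma event), which leaves the trace statistic unchanged.

Exon boundaries in the expression tables are jittered by up to ±2 nt to
exercise the ±5 nt boundary-matching margin.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FixtureManifest", "generate_fixtures"]

_BASELINE = 50.0
_SCALE = 5.0
_CONDITIONS = ("normal", "disease")

# planted inter-gene edge sets (the differential-network worked example):
# normal-only edge A1-B3 is "lost" in disease, disease-only A1-B2 is "gained"
_PLANTED_EDGES = {
    "normal": (("GENEA:A1", "GENEB:B1"), ("GENEA:A1", "GENEB:B3"), ("GENEA:A2", "GENEB:B3")),
    "disease": (("GENEA:A1", "GENEB:B1"), ("GENEA:A1", "GENEB:B2"), ("GENEA:A2", "GENEB:B3")),
}


@dataclass
class FixtureManifest:
    """Everything needed to recompute the fixture files and their ground truth."""

    seed: int
    n_samples: int
    edge_c0: float
    exons_per_isoform: int
    jitter_nt: int
    paths: dict[str, str]
    genes: dict[str, dict[str, list[list[int]]]]  # gene -> isoform -> exon [start, end)
    shared_exons: dict[str, list[str]]  # "chrom:start-end" -> [gene:isoform, ...]
    planted_edges: dict[str, list[list[str]]]
    samples: dict[str, list[str]]
    isoform_abundance: dict[str, dict[str, list[float]]]  # condition -> isoform -> per-sample
    raw_exon_values: dict[str, dict[str, list[float]]]  # condition -> exon key -> per-sample
    ground_truth_cex: dict[str, dict[str, list[list[float]]]] = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "FixtureManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_structures(exons_per_isoform: int) -> dict[str, dict[str, list[list[int]]]]:
    """Fixed gene models: GENEA (2 isoforms) and GENEB (3) have private exons;
    GENEC and GENED each have 2 isoforms sharing all but their last exon."""
    genes: dict[str, dict[str, list[list[int]]]] = {}
    cursor = 10_000
    step = 1_000

    def fresh_exons(k):
        nonlocal cursor
        out = []
        for _ in range(k):
            out.append([cursor, cursor + 200])
            cursor += step
        return out

    genes["GENEA"] = {f"A{i + 1}": fresh_exons(exons_per_isoform) for i in range(2)}
    genes["GENEB"] = {f"B{i + 1}": fresh_exons(exons_per_isoform) for i in range(3)}
    for gene, prefix in (("GENEC", "C"), ("GENED", "D")):
        shared = fresh_exons(exons_per_isoform - 1)
        genes[gene] = {
            f"{prefix}1": shared + fresh_exons(1),
            f"{prefix}2": [list(e) for e in shared] + fresh_exons(1),
        }
        for iso in genes[gene].values():
            iso.sort(key=lambda e: e[0])
    return genes


def _write_annotation(genes: dict, path: str) -> None:
    rows = []
    for gene, isoforms in sorted(genes.items()):
        for iso, exons in sorted(isoforms.items()):
            exons = sorted(exons, key=lambda e: e[0])
            rows.append(
                {
                    "geneName": gene,
                    "name": iso,
                    "chrom": "chr1",
                    "strand": "+",
                    "exonStarts": ",".join(str(e[0]) for e in exons) + ",",
                    "exonEnds": ",".join(str(e[1]) for e in exons) + ",",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def generate_fixtures(
    outdir: str,
    seed: int = 0,
    n_samples: int = 100,
    edge_c0: float = 0.6,
    exons_per_isoform: int = 5,
    jitter_nt: int = 2,
) -> FixtureManifest:
    """Write annotation + per-condition expression fixtures; return the manifest."""
    if n_samples < 10:
        raise ValueError("need at least 10 samples for a meaningful fixture")
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = _gene_structures(exons_per_isoform)

    # shared-exon registry (exact coordinate identity inside the generator)
    shared: dict[str, list[str]] = {}
    for gene, isoforms in sorted(genes.items()):
        for iso, exons in sorted(isoforms.items()):
            for s, e in exons:
                shared.setdefault(f"chr1:{s}-{e}", []).append(f"{gene}:{iso}")

    all_isoforms = [f"{g}:{i}" for g in sorted(genes) for i in sorted(genes[g])]
    loading = float(np.sqrt(edge_c0 * (1.0 + edge_c0)))

    paths = {"annotation": os.path.join(outdir, "annotation.tsv")}
    _write_annotation(genes, paths["annotation"])

    samples: dict[str, list[str]] = {}
    abundance: dict[str, dict[str, list[float]]] = {}
    raw_values: dict[str, dict[str, list[float]]] = {}
    cex: dict[str, dict[str, list[list[float]]]] = {}

    for cond in _CONDITIONS:
        sample_ids = [f"{cond[0].upper()}{k:03d}" for k in range(n_samples)]
        samples[cond] = sample_ids

        # latent per-isoform exon signals plus per-edge shared factors
        latent = {
            iso: rng.standard_normal((exons_per_isoform, n_samples)) for iso in all_isoforms
        }
        for u, v in _PLANTED_EDGES[cond]:
            factor = rng.standard_normal((exons_per_isoform, n_samples))
            latent[u] = latent[u] + loading * factor
            latent[v] = latent[v] + loading * factor

        # isoform abundances: positive, lognormal
        abundance[cond] = {
            iso: np.round(rng.lognormal(mean=1.0, sigma=0.5, size=n_samples), 4).tolist()
            for iso in all_isoforms
        }

        # raw exon values: sum the (affine-mapped) latent signal over the
        # isoforms carrying the exon, weighted by nothing — the measured total
        raw_values[cond] = {}
        for key, carriers in shared.items():
            total = np.zeros(n_samples)
            for carrier in carriers:
                gene, iso = carrier.split(":")
                exons = sorted(genes[gene][iso], key=lambda e: e[0])
                s, e = map(int, key.split(":")[1].split("-"))
                idx = exons.index([s, e])
                total += np.clip(_BASELINE + _SCALE * latent[carrier][idx], 0.0, None)
            raw_values[cond][key] = np.round(total, 4).tolist()

        # ground-truth corrected matrices via the abundance-split formula
        cex[cond] = {}
        for carrier in all_isoforms:
            gene, iso = carrier.split(":")
            exons = sorted(genes[gene][iso], key=lambda e: e[0])
            mat = np.empty((len(exons), n_samples))
            for r, (s, e) in enumerate(exons):
                key = f"chr1:{s}-{e}"
                carriers = shared[key]
                raw = np.asarray(raw_values[cond][key])
                if len(carriers) == 1:
                    mat[r] = raw
                else:
                    own = np.asarray(abundance[cond][carrier])
                    tot = np.sum([abundance[cond][c] for c in carriers], axis=0)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        mat[r] = np.where(tot > 0, raw * own / tot, 0.0)
            cex[cond][carrier] = np.round(mat, 6).tolist()

        # long-format expression tables (boundaries jittered within the margin)
        exon_rows = []
        for key in sorted(shared, key=lambda k: int(k.split(":")[1].split("-")[0])):
            s, e = map(int, key.split(":")[1].split("-"))
            ds = int(rng.integers(-jitter_nt, jitter_nt + 1)) if jitter_nt else 0
            de = int(rng.integers(-jitter_nt, jitter_nt + 1)) if jitter_nt else 0
            for k, sid in enumerate(sample_ids):
                exon_rows.append(
                    {"sample_id": sid, "chrom": "chr1", "start": s + ds, "end": e + de,
                     "strand": "+", "value": raw_values[cond][key][k]}
                )
        iso_rows = [
            {"sample_id": sid, "isoform_id": iso.split(":")[1], "value": abundance[cond][iso][k]}
            for iso in all_isoforms
            for k, sid in enumerate(samples[cond])
        ]
        paths[f"{cond}_exon"] = os.path.join(outdir, f"{cond}.exon.tsv")
        paths[f"{cond}_isoform"] = os.path.join(outdir, f"{cond}.isoform.tsv")
        pd.DataFrame(exon_rows).to_csv(paths[f"{cond}_exon"], sep="\t", index=False)
        pd.DataFrame(iso_rows).to_csv(paths[f"{cond}_isoform"], sep="\t", index=False)

    manifest = FixtureManifest(
        seed=seed,
        n_samples=n_samples,
        edge_c0=edge_c0,
        exons_per_isoform=exons_per_isoform,
        jitter_nt=jitter_nt,
        paths=paths,
        genes=genes,
        shared_exons=shared,
        planted_edges={c: [list(e) for e in _PLANTED_EDGES[c]] for c in _CONDITIONS},
        samples=samples,
        isoform_abundance=abundance,
        raw_exon_values=raw_values,
        ground_truth_cex=cex,
    )
    paths["manifest"] = os.path.join(outdir, "manifest.json")
    manifest.save(paths["manifest"])
    return manifest
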