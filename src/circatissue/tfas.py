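"""ChIP-seq peak-to-gene association and TFAS target calling.

Peaks are matched to genes on the same chromosome whenever the distance
between the peak center and the first base of the gene's start codon is
strictly below a maximum (default 5 kb).  Each gene then receives a
transcription-factor association score

    TFAS(gene) = sum over associated peaks of score * exp(-distance/d0)

with the length scale ``d0`` defaulting to 500 bp.  Target sets for two
factors A and B (e.g. an E-box activator and an RRE repressor) are the
genes whose TFAS strictly exceeds the per-factor cutoff; the three
reported lists — A-only, B-only, and A-and-B — partition the union.

Peak files are BED (0-based half-open intervals, score in column 5);
the gene annotation is a BED-like table whose interval is the 1 bp
start-codon position, with the gene identifier in the name column and
strand in column 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "read_peaks_bed",
    "read_gene_annotation",
    "assign_peaks_to_genes",
    "compute_tfas",
    "build_target_sets",
    "TargetSets",
    "target_genes",
]

_BED_PEAK_COLS = ["chrom", "start", "end", "name", "score"]
_BED_GENE_COLS = ["chrom", "start", "end", "gene", "score", "strand"]


def read_peaks_bed(path) -> pd.DataFrame:
    """Load a 5-column BED peak file; adds the ``center`` column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=_BED_PEAK_COLS,
                     usecols=range(len(_BED_PEAK_COLS)))
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED peaks must satisfy start < end")
    if (df["score"] < 0).any():
        raise ValueError("peak scores must be non-negative")
    df["center"] = (df["start"] + df["end"]) / 2.0
    return df


def read_gene_annotation(path) -> pd.DataFrame:
    """Load a BED-like annotation whose interval marks the start codon.

    The first base of the start codon is the interval start (0-based);
    strand must be ``+`` or ``-``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=_BED_GENE_COLS,
                     usecols=range(len(_BED_GENE_COLS)))
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if (df["start"] < 0).any():
        raise ValueError("coordinates must be non-negative")
    df = df.rename(columns={"start": "start_codon"})
    return df[["gene", "chrom", "strand", "start_codon"]]


def assign_peaks_to_genes(peaks: pd.DataFrame, annotation: pd.DataFrame,
                          max_distance: float = 5000.0):
    """All (peak, gene) pairs closer than ``max_distance`` (strict).

    Distance is the unstranded absolute difference between the peak
    center and the start-codon base.  Returns ``(associations,
    gene2peak_count, peak2gene_count, n_skipped_peaks)``: the mapping
    counts cover every gene/peak (zero when unmatched) and peaks on
    chromosomes absent from the annotation are skipped and counted.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    known_chroms = set(annotation["chrom"])
    n_skipped = int((~peaks["chrom"].isin(known_chroms)).sum())

    rows = []
    for chrom, gsub in annotation.groupby("chrom", sort=False):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            continue
        gpos = gsub["start_codon"].to_numpy(float)
        centers = psub["center"].to_numpy(float)
        order = np.argsort(gpos)
        gpos_sorted = gpos[order]
        lo = np.searchsorted(gpos_sorted, centers - max_distance, "right")
        hi = np.searchsorted(gpos_sorted, centers + max_distance, "left")
        for k, (pidx, c) in enumerate(zip(psub.index, centers)):
            for j in range(lo[k], hi[k]):
                gi = gsub.index[order[j]]
                dist = abs(c - gpos_sorted[j])
                if dist < max_distance:        # strict boundary
                    rows.append((gsub.at[gi, "gene"], pidx, dist,
                                 peaks.at[pidx, "score"]))
    assoc = pd.DataFrame(rows, columns=["gene", "peak_index", "distance",
                                        "score"])
    gene2peak = assoc.groupby("gene").size().reindex(
        annotation["gene"], fill_value=0).astype(int)
    gene2peak.name = "gene2peak.mapped.count"
    peak2gene = assoc.groupby("peak_index").size().reindex(
        peaks.index, fill_value=0).astype(int)
    peak2gene.name = "peak2gene.mapped.count"
    return assoc, gene2peak, peak2gene, n_skipped


def compute_tfas(associations: pd.DataFrame, annotation: pd.DataFrame,
                 d0: float = 500.0) -> pd.Series:
    """Per-gene TFAS: distance-discounted sum of associated peak scores."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    contrib = associations["score"] * np.exp(-associations["distance"] / d0)
    tfas = contrib.groupby(associations["gene"]).sum()
    tfas = tfas.reindex(annotation["gene"], fill_value=0.0)
    tfas.name = "tfas"
    return tfas


@dataclass
class TargetSets:
    """Disjoint factor target lists partitioning the union."""

    a_only: list
    b_only: list
    both: list

    @property
    def union(self) -> list:
        return sorted(set(self.a_only) | set(self.b_only) | set(self.both))


def target_genes(tfas: pd.Series, cutoff: float) -> set:
    """Genes whose TFAS strictly exceeds the cutoff."""
    return set(tfas.index[tfas > cutoff])


def build_target_sets(tfas_a, tfas_b,
                      cutoff_a: float = 10.0,
                      cutoff_b: float = 0.5) -> TargetSets:
    """Exclusive and joint target sets of two factors.

    ``tfas_a``/``tfas_b`` may each be a single per-gene TFAS series or a
    list of series from replicate peak files; with replicates a gene is
    a factor target if it clears the cutoff in any replicate (union
    rule).
    """
    def _targets(t, cutoff):
        if isinstance(t, pd.Series):
            t = [t]
        out = set()
        for series in t:
            out |= target_genes(series, cutoff)
        return out

    a = _targets(tfas_a, cutoff_a)
    b = _targets(tfas_b, cutoff_b)
    return TargetSets(sorted(a - b), sorted(b - a), sorted(a & b))
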