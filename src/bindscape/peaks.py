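"""Peak-set comparison: Jaccard footprinting, target partitioning, gene assignment.

The comparative analysis of a wild-type transcription factor against its
variants rests on three operations over binding-peak sets:

* a base-pair Jaccard similarity between two peak sets (intersection bp over
  union bp), assembled into a symmetric matrix over all alleles;
* an A/B/C partition of a WT-vs-variant pair — A: peaks bound only by WT
  (lost targets), B: peaks bound by both (retained), C: peaks bound only by
  the variant (off-target gains);
* GREAT-style "basal plus extension" peak-to-gene assignment (basal domain
  6.5 kb upstream / 2.5 kb downstream of the TSS, extended to the nearest
  neighbouring basal domain or at most 100 kb from the TSS), with a peak
  assigned to every gene whose regulatory domain contains the peak midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "GeneModel",
    "TargetPartition",
    "JaccardMatrix",
    "jaccard",
    "jaccard_matrix",
    "classify_targets",
    "assign_genes",
    "regulatory_domains",
    "partition_gene_sets",
    "read_gene_table",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class TargetPartition:
    """A/B/C partition of a WT-vs-variant peak comparison.

    ``b_peaks`` is reported from the WT side (WT peaks overlapping any variant
    peak); ``b_peaks_variant`` holds the variant-side twins so gene unions can
    draw on both.
    """

    a_peaks: PeakSet
    b_peaks: PeakSet
    c_peaks: PeakSet
    b_peaks_variant: PeakSet
    a_genes: set[str] = field(default_factory=set)
    b_genes: set[str] = field(default_factory=set)
    c_genes: set[str] = field(default_factory=set)

    def summary(self) -> dict:
        return {
            "n_a_peaks": len(self.a_peaks),
            "n_b_peaks": len(self.b_peaks),
            "n_c_peaks": len(self.c_peaks),
            "n_a_genes": len(self.a_genes),
            "n_b_genes": len(self.b_genes),
            "n_c_genes": len(self.c_genes),
        }


@dataclass
class JaccardMatrix:
    labels: list[str]
    values: np.ndarray
    flagged: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def _intersection_bp(a: PeakSet, b: PeakSet) -> int:
    """Total overlapping bp between two merged peak sets (two-pointer sweep)."""
    a_by, b_by = a.by_chrom(), b.by_chrom()
    total = 0
    for chrom in set(a_by) & set(b_by):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i, 0], ys[j, 0])
            hi = min(xs[i, 1], ys[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if xs[i, 1] <= ys[j, 1]:
                i += 1
            else:
                j += 1
    return total


def jaccard(a: PeakSet, b: PeakSet) -> float:
    """Base-pair Jaccard similarity: intersection bp / union bp."""
    bp_a, bp_b = a.total_bp, b.total_bp
    if bp_a == 0 and bp_b == 0:
        raise ValueError("Jaccard undefined: both peak sets are empty")
    inter = _intersection_bp(a, b)
    return inter / (bp_a + bp_b - inter)


def jaccard_matrix(sets: Sequence[PeakSet]) -> JaccardMatrix:
    """All pairwise Jaccard similarities over a collection of peak sets.

    Empty sets are flagged (their rows/columns are NaN off-diagonal), never
    silently reported as zero similarity.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 peak sets")
    n = len(sets)
    labels = [s.allele for s in sets]
    vals = np.ones((n, n))
    flagged = [s.allele for s in sets if s.total_bp == 0]
    for i in range(n):
        if sets[i].total_bp == 0:
            vals[i, :] = np.nan
            vals[:, i] = np.nan
            continue
        for j in range(i + 1, n):
            if sets[j].total_bp == 0:
                continue
            vals[i, j] = vals[j, i] = jaccard(sets[i], sets[j])
    return JaccardMatrix(labels, vals, flagged)


def _max_overlap_with(set_by_chrom: dict[str, np.ndarray], iv: GenomicInterval) -> int:
    arr = set_by_chrom.get(iv.chrom)
    if arr is None:
        return 0
    lo = np.maximum(arr[:, 0], iv.start)
    hi = np.minimum(arr[:, 1], iv.end)
    ov = hi - lo
    return int(ov.max(initial=0))


def classify_targets(
    wt: PeakSet, variant: PeakSet, min_overlap_bp: int = 1
) -> TargetPartition:
    """Partition peaks into lost (A), retained (B) and off-target (C) sets.

    A WT peak is B if it overlaps any variant peak by at least
    ``min_overlap_bp``, else A. A variant peak overlapping no WT peak by at
    least ``min_overlap_bp`` is C.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    var_by = variant.by_chrom()
    wt_by = wt.by_chrom()
    a_ivs, b_ivs, c_ivs, b_var_ivs = [], [], [], []
    for iv in wt:
        (b_ivs if _max_overlap_with(var_by, iv) >= min_overlap_bp else a_ivs).append(iv)
    for iv in variant:
        if _max_overlap_with(wt_by, iv) >= min_overlap_bp:
            b_var_ivs.append(iv)
        else:
            c_ivs.append(iv)
    return TargetPartition(
        a_peaks=PeakSet(f"{wt.allele}_A", a_ivs, merge=False),
        b_peaks=PeakSet(f"{wt.allele}_B", b_ivs, merge=False),
        c_peaks=PeakSet(f"{variant.allele}_C", c_ivs, merge=False),
        b_peaks_variant=PeakSet(f"{variant.allele}_B", b_var_ivs, merge=False),
    )


def regulatory_domains(
    genes: Sequence[GeneModel],
    basal_up: int = 6500,
    basal_down: int = 2500,
    max_ext: int = 100000,
) -> dict[str, tuple[int, int]]:
    """Per-gene regulatory domain [start, end) under basal-plus-extension.

    The basal domain is strand-aware (basal_up upstream of the TSS, basal_down
    downstream). Each basal domain is then extended in both directions to the
    nearest neighbouring basal domain edge, capped at max_ext from the TSS,
    whichever is closer. Extensions of neighbouring genes may overlap in the
    gap between their basal domains (a peak there is assigned to both), and a
    base pair can belong to at most the two flanking genes' domains plus any
    basal domains that themselves overlap.
    """
    basal: dict[str, tuple[int, int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.strand == "+":
            b = (max(0, g.tss - basal_up), g.tss + basal_down)
        else:
            b = (max(0, g.tss - basal_down), g.tss + basal_up)
        basal[g.gene_id] = b
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: dict[str, tuple[int, int]] = {}
    for chrom, gs in by_chrom.items():
        for g in gs:
            b_lo, b_hi = basal[g.gene_id]
            lo = max(0, g.tss - max_ext)
            hi = g.tss + max_ext
            # an extension stops where any other gene's basal domain begins;
            # a neighbouring basal reaching into this gene's basal truncates
            # the extension to nothing on that side
            for o in gs:
                if o.gene_id == g.gene_id:
                    continue
                o_lo, o_hi = basal[o.gene_id]
                if o_lo < b_lo:  # occupies space left of this basal
                    lo = max(lo, min(o_hi, b_lo))
                if o_hi > b_hi:  # occupies space right of this basal
                    hi = min(hi, max(o_lo, b_hi))
            domains[g.gene_id] = (min(lo, b_lo), max(hi, b_hi))
    return domains


def assign_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    basal_up: int = 6500,
    basal_down: int = 2500,
    max_ext: int = 100000,
) -> dict[GenomicInterval, set[str]]:
    """Assign each peak to every gene whose regulatory domain contains its midpoint."""
    peak_chroms = {iv.chrom for iv in peaks}
    usable = []
    for g in genes:
        if peak_chroms and g.chrom not in peak_chroms:
            warnings.warn(
                f"gene {g.gene_id} on chromosome {g.chrom} absent from peak set; skipped"
            )
            continue
        usable.append(g)
    domains = regulatory_domains(usable, basal_up, basal_down, max_ext)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in usable:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    assignment: dict[GenomicInterval, set[str]] = {}
    for iv in peaks:
        mid = iv.midpoint
        hits = set()
        for g in genes_by_chrom.get(iv.chrom, []):
            lo, hi = domains[g.gene_id]
            if lo <= mid < hi:
                hits.add(g.gene_id)
        assignment[iv] = hits
    return assignment


def partition_gene_sets(
    partition: TargetPartition,
    assignment: Mapping[GenomicInterval, set[str]],
) -> TargetPartition:
    """Fill gene-level A/B/C sets from a peak->genes assignment.

    B genes draw on both the WT-side B peaks and their variant-side twins.
    """

    def union(peaks: Iterable[GenomicInterval]) -> set[str]:
        out: set[str] = set()
        for iv in peaks:
            out |= assignment.get(iv, set())
        return out

    partition.a_genes = union(partition.a_peaks)
    partition.b_genes = union(partition.b_peaks) | union(partition.b_peaks_variant)
    partition.c_genes = union(partition.c_peaks)
    return partition


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV of (gene_id, chrom, tss, strand) into GeneModel records."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    return [
        GeneModel(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]
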