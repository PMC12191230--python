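"""k-mer motif scanning, flanking-base preference, motif classes, enrichment.

The homeodomain binding element at the centre of this analysis is the NKE
core CACTT. Its affinity is modulated by the immediately flanking bases:
a 5'-C (CCACTT) marks the high-affinity form, while a 3'-T (CACTTT) and
other flank conformations mark the low-affinity form. 8-mers are classed as
high_NKE / low_NKE / HOX_like (containing the homeodomain TAAT core) /
other, and class composition between conditions is compared with two-sided
Fisher's exact tests. Motif enrichment against a dinucleotide-preserving
shuffle null is summarised as a permutation Z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "MotifSpec",
    "FlankTable",
    "revcomp",
    "scan_kmer",
    "flank_preference",
    "assign_motif_class",
    "compare_class_proportions",
    "filter_peaks_by_motif_count",
    "enrichment_z",
    "dinucleotide_shuffle",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: core motifs, in class precedence order
HIGH_NKE_CORE = "CCACTT"
NKE_CORE = "CACTT"
HOX_CORE = "TAAT"

MOTIF_CLASSES = ("high_NKE", "low_NKE", "HOX_like", "other")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    name: str
    kmer: str
    class_label: str = "other"

    def __post_init__(self) -> None:
        if len(self.kmer) < 4:
            raise ValueError("motif k-mer must be at least 4 nt")
        if set(self.kmer) - set("ACGT"):
            raise ValueError("motif k-mer must be over {A,C,G,T}")
        if self.class_label not in MOTIF_CLASSES:
            raise ValueError(f"class_label must be one of {MOTIF_CLASSES}")


@dataclass
class FlankTable:
    """Counts of the immediate 5' and 3' bases around a core k-mer.

    Rows are bases A/C/G/T; columns are the 5' and 3' flank positions.
    Flanks are read on the strand of the core match; edge occurrences
    contribute only the flank they have, so the two column sums may differ.
    """

    core: str
    counts: pd.DataFrame  # index A,C,G,T; columns "5p","3p"
    n_hits: int

    def modal_base(self, side: str) -> str:
        return str(self.counts[side].idxmax())


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) match offsets of needle in haystack."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_kmer(sequence: str, motif: MotifSpec | str) -> list[tuple[int, str]]:
    """Exact occurrences of a k-mer on both strands of a sequence.

    Returns (offset, strand) pairs, offsets on the forward sequence,
    overlapping matches included. 'N' never matches. A palindromic k-mer is
    reported once per offset (forward).
    """
    kmer = motif.kmer if isinstance(motif, MotifSpec) else motif
    seq = sequence.upper()
    hits = [(i, "+") for i in _find_all(seq, kmer)]
    rc = revcomp(kmer)
    if rc != kmer:
        hits += [(i, "-") for i in _find_all(seq, rc)]
    return sorted(hits)


def flank_preference(sequences: Sequence[str], core: str = NKE_CORE) -> FlankTable:
    """Tally the immediate 5' and 3' bases around every core occurrence.

    The core is matched on both strands; flanks are read on the matched
    strand (for a reverse-strand match, the 5' flank is the complement of
    the base after the match on the forward strand).
    """
    counts = {b: {"5p": 0, "3p": 0} for b in "ACGT"}
    n_hits = 0
    k = len(core)
    for seq in sequences:
        seq = seq.upper()
        for off, strand in scan_kmer(seq, MotifSpec("core", core)):
            if strand == "+":
                five = seq[off - 1] if off > 0 else None
                three = seq[off + k] if off + k < len(seq) else None
            else:
                five = (
                    seq[off + k].translate(_COMPLEMENT) if off + k < len(seq) else None
                )
                three = seq[off - 1].translate(_COMPLEMENT) if off > 0 else None
            if five is None and three is None:
                continue
            n_hits += 1
            if five in counts:
                counts[five]["5p"] += 1
            if three in counts:
                counts[three]["3p"] += 1
    if n_hits == 0:
        raise ValueError(f"no flanked occurrence of core {core!r} in input sequences")
    df = pd.DataFrame(counts).T.loc[list("ACGT"), ["5p", "3p"]]
    return FlankTable(core=core, counts=df, n_hits=n_hits)


def _contains_either_strand(seq: str, core: str) -> bool:
    return core in seq or revcomp(core) in seq


def assign_motif_class(kmer8: str) -> str:
    """Class label for an 8-mer: high_NKE > low_NKE > HOX_like > other.

    high_NKE: contains the high-affinity flanked core CCACTT (either strand);
    low_NKE: contains the bare NKE core CACTT; HOX_like: contains the
    homeodomain TAAT core. Precedence is fixed in that order, so the
    assignment is total and strand-invariant.
    """
    kmer8 = kmer8.upper()
    if len(kmer8) != 8 or set(kmer8) - set("ACGT"):
        raise ValueError("expected an 8-mer over {A,C,G,T}")
    if _contains_either_strand(kmer8, HIGH_NKE_CORE):
        return "high_NKE"
    if _contains_either_strand(kmer8, NKE_CORE):
        return "low_NKE"
    if _contains_either_strand(kmer8, HOX_CORE):
        return "HOX_like"
    return "other"


def compare_class_proportions(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> pd.DataFrame:
    """Per-class odds ratio and two-sided Fisher exact p, class vs rest.

    For each class the 2x2 table is [[a_class, a_rest], [b_class, b_rest]].
    Classes whose table has an all-zero margin get NaN p / odds ratio.
    """
    classes = sorted(set(counts_a) | set(counts_b))
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    rows = []
    for cls in classes:
        ca, cb = int(counts_a.get(cls, 0)), int(counts_b.get(cls, 0))
        table = np.array([[ca, tot_a - ca], [cb, tot_b - cb]])
        if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
            odds, p = np.nan, np.nan
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {"class": cls, "count_a": ca, "count_b": cb, "odds_ratio": odds, "p": p}
        )
    return pd.DataFrame(rows).set_index("class")


def filter_peaks_by_motif_count(
    peaks: PeakSet,
    sequences: Mapping[str, str],
    motif: MotifSpec | str,
    min_count: int = 3,
) -> PeakSet:
    """Retain peaks whose sequence carries >= min_count motif occurrences.

    Occurrences are counted on both strands. Sequences are keyed by peak
    name; a peak without a sequence is an error, not a silent drop.
    """
    kept: list[GenomicInterval] = []
    for iv in peaks:
        key = iv.name
        if key is None or key not in sequences:
            raise KeyError(
                f"no sequence for peak {key or f'{iv.chrom}:{iv.start}-{iv.end}'}"
            )
        if len(scan_kmer(sequences[key], motif)) >= min_count:
            kept.append(iv)
    return PeakSet(peaks.allele, kept, merge=False)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Rejection-sampled Eulerian walk on the dinucleotide transition graph:
    each vertex's outgoing-edge list is permuted uniformly, and the walk from
    the original start symbol is accepted iff it consumes every edge (which
    guarantees the original start/end symbols and the exact dinucleotide
    multiset are preserved). Acceptance probability is bounded away from
    zero on a 4-letter alphabet, so the retry loop terminates quickly.
    """
    if len(seq) <= 3:
        return seq
    seq = seq.upper()
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    for _ in range(10000):
        order = {v: [outs[i] for i in rng.permutation(len(outs))]
                 for v, outs in edges.items()}
        ptr = dict.fromkeys(edges, 0)
        out = [seq[0]]
        v = seq[0]
        while v in ptr and ptr[v] < len(order[v]):
            nxt = order[v][ptr[v]]
            ptr[v] += 1
            out.append(nxt)
            v = nxt
        if len(out) == n_edges + 1:
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")


def enrichment_z(
    peaks: PeakSet | None,
    sequences: Mapping[str, str] | Sequence[str],
    motif: MotifSpec | str,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation Z-score of total motif count vs dinucleotide-shuffled null.

    The observed statistic is the total occurrence count (both strands) over
    all peak sequences; the null distribution comes from per-sequence
    dinucleotide-preserving shuffles. Z = (obs - mean_null) / sd_null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(sequences, Mapping):
        if peaks is not None:
            seqs = [sequences[iv.name] for iv in peaks]
        else:
            seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    rng = np.random.default_rng(seed)
    obs = sum(len(scan_kmer(s, motif)) for s in seqs)
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = sum(
            len(scan_kmer(dinucleotide_shuffle(s, rng), motif)) for s in seqs
        )
    sd = null.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate null (sd=0); Z reported as +/-inf")
        diff = obs - null.mean()
        return float(np.inf if diff > 0 else (-np.inf if diff < 0 else 0.0))
    return float((obs - null.mean()) / sd)
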