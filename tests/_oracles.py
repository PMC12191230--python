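"""Independent brute-force oracles used across the test suite.

Each oracle re-derives an expected value by the most direct method available
(per-base-pair boolean arrays, naive sliding windows, O(n^2) pair counting,
exact enumeration), deliberately sharing no code with the implementation it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def bp_jaccard(a_intervals, b_intervals, chrom_len: int, chroms) -> float:
    """Per-base-pair boolean-array Jaccard over a toy genome."""
    inter = union = 0
    for chrom in chroms:
        a = np.zeros(chrom_len, dtype=bool)
        b = np.zeros(chrom_len, dtype=bool)
        for c, s, e in a_intervals:
            if c == chrom:
                a[s:e] = True
        for c, s, e in b_intervals:
            if c == chrom:
                b[s:e] = True
        inter += int((a & b).sum())
        union += int((a | b).sum())
    return inter / union


def naive_kmer_scan(seq: str, kmer: str) -> list[tuple[int, str]]:
    """Sliding-window scan of kmer and its reverse complement."""
    hits = []
    k = len(kmer)
    kr = rc(kmer)
    for i in range(len(seq) - k + 1):
        window = seq[i: i + k]
        if window == kmer:
            hits.append((i, "+"))
        if kr != kmer and window == kr:
            hits.append((i, "-"))
    return sorted(hits)


def pair_count_escore(sequences, intensities, kmer8: str) -> float:
    """O(n^2) pair-counting E-score oracle.

    Foreground = probes containing the 8-mer or its reverse complement; the
    brighter ceil(n/2) of each group enter the pair count; ties credit 1/2.
    """
    kr = rc(kmer8)
    fg, bg = [], []
    for seq, inten in zip(sequences, intensities):
        if "N" in seq:
            continue
        (fg if (kmer8 in seq or kr in seq) else bg).append(inten)
    if not fg or not bg:
        return float("nan")
    fg = sorted(fg, reverse=True)[: math.ceil(len(fg) / 2)]
    bg = sorted(bg, reverse=True)[: math.ceil(len(bg) / 2)]
    u = 0.0
    for f in fg:
        for b in bg:
            if f > b:
                u += 1.0
            elif f == b:
                u += 0.5
    return u / (len(fg) * len(bg)) - 0.5


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Table [[a, b], [c, d]]; sums probabilities of all tables with the same
    margins whose probability does not exceed that of the observed table.
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_p(x: int) -> float:
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    p_obs = table_p(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(
        p for x in range(lo, hi + 1) if (p := table_p(x)) <= p_obs * (1 + 1e-9)
    )


def gene_domains_per_bp(genes, chrom_len, basal_up=6500, basal_down=2500,
                        max_ext=100000):
    """Per-bp map bp -> set of gene ids whose regulatory domain covers it.

    A bp belongs to gene g if it is in g's basal domain, or in the extension:
    between g's basal domain and the cap (max_ext from the TSS) with no other
    gene's basal domain lying strictly between the bp and g's basal domain.
    genes: list of (gene_id, tss, strand) on one chromosome.
    """
    basal = {}
    for gid, tss, strand in genes:
        if strand == "+":
            basal[gid] = (max(0, tss - basal_up), tss + basal_down)
        else:
            basal[gid] = (max(0, tss - basal_down), tss + basal_up)
    covering = [set() for _ in range(chrom_len)]
    for gid, tss, strand in genes:
        b_lo, b_hi = basal[gid]
        lo_cap = max(0, tss - max_ext)
        hi_cap = min(chrom_len, tss + max_ext)
        for bp in range(lo_cap, min(hi_cap, chrom_len)):
            if b_lo <= bp < b_hi:
                covering[bp].add(gid)
                continue
            if bp < b_lo:
                # blocked if another basal domain intersects (bp, b_lo)
                blocked = any(
                    other != gid
                    and basal[other][1] > bp
                    and basal[other][0] < b_lo
                    for other in basal
                )
            else:
                # blocked if another basal domain intersects (b_hi, bp]
                blocked = any(
                    other != gid
                    and basal[other][0] <= bp
                    and basal[other][1] > b_hi
                    for other in basal
                )
            if not blocked:
                covering[bp].add(gid)
    return covering
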