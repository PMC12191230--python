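"""Rank-based 8-mer enrichment scores (E-scores) from PBM probe intensities.

A protein-binding microarray measures a TF's affinity for every 8-mer
indirectly: each double-stranded probe carries many overlapping 8-mers, and
the enrichment score of an 8-mer compares the intensity ranks of probes that
contain it (foreground) against probes that do not (background). Following
the universal-array convention, only the brighter half of each group enters
a Mann-Whitney-style pair count U, and

    E = U / (n_f * n_b) - 0.5,   E in [-0.5, 0.5],

so E = +0.5 means every retained foreground probe outranks every retained
background probe. Because E is rank-based it is invariant to any strictly
monotone transform of the intensities, which makes the downstream comparison
of wild-type and variant binding landscapes insensitive to array
normalisation details. 8-mers are collapsed with their reverse complements
(a double-stranded probe cannot distinguish them); E > 0.35 is the
conventional significance cut-off.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import assign_motif_class, revcomp

__all__ = [
    "EscoreTable",
    "collapse_kmer",
    "escore",
    "escore_table",
    "compare_landscapes",
    "read_probe_table",
    "write_probe_table",
]

SIGNIFICANCE_CUTOFF = 0.35


def collapse_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class EscoreTable:
    """Map from reverse-complement-collapsed 8-mer to its E-score."""

    scores: pd.Series  # index: collapsed 8-mer, values: E in [-0.5, 0.5]
    n_fg: pd.Series = field(default=None)  # foreground probe count per 8-mer

    def __post_init__(self) -> None:
        if self.n_fg is None:
            self.n_fg = pd.Series(np.nan, index=self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, kmer: str) -> float:
        return float(self.scores[collapse_kmer(kmer.upper())])

    def significant(self, cutoff: float = SIGNIFICANCE_CUTOFF) -> set[str]:
        return set(self.scores.index[self.scores > cutoff])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"escore": self.scores, "n_fg": self.n_fg}).rename_axis(
            "kmer8"
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EscoreTable":
        df = pd.read_csv(path, index_col="kmer8")
        return cls(df["escore"], df["n_fg"])


def _clean_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Uppercase sequences; drop probes containing N (excluded from both groups)."""
    df = probes.copy()
    df["sequence"] = df["sequence"].str.upper()
    return df[~df["sequence"].str.contains("N")].reset_index(drop=True)


def _half_top(values: np.ndarray) -> np.ndarray:
    """The larger ceil(n/2) of a 1-D array."""
    k = math.ceil(len(values) / 2)
    return np.sort(values)[len(values) - k:]


def _pair_u(fg: np.ndarray, bg: np.ndarray) -> float:
    """Mann-Whitney count of (fg, bg) pairs with fg higher; ties count 1/2."""
    bg_sorted = np.sort(bg)
    lo = np.searchsorted(bg_sorted, fg, side="left")
    hi = np.searchsorted(bg_sorted, fg, side="right")
    return float(lo.sum() + 0.5 * (hi - lo).sum())


def escore(probes: pd.DataFrame, kmer8: str) -> float:
    """E-score of one 8-mer against a probe table.

    Foreground: probes containing the 8-mer or its reverse complement;
    background: all other probes. The brighter ceil(n/2) probes of each
    group are retained before the pair count. NaN when either group is
    empty.
    """
    kmer8 = kmer8.upper()
    if len(kmer8) != 8 or set(kmer8) - set("ACGT"):
        raise ValueError("kmer8 must be an 8-mer over {A,C,G,T}")
    df = _clean_probes(probes)
    rc = revcomp(kmer8)
    in_fg = df["sequence"].str.contains(kmer8, regex=False)
    if rc != kmer8:
        in_fg |= df["sequence"].str.contains(rc, regex=False)
    fg_all = df.loc[in_fg, "intensity"].to_numpy(float)
    bg_all = df.loc[~in_fg, "intensity"].to_numpy(float)
    if len(fg_all) == 0 or len(bg_all) == 0:
        return float("nan")
    fg = _half_top(fg_all)
    bg = _half_top(bg_all)
    return _pair_u(fg, bg) / (len(fg) * len(bg)) - 0.5


def _kmer_index(sequences: pd.Series, k: int = 8) -> dict[str, np.ndarray]:
    """Map collapsed k-mer -> array of probe row indices containing it."""
    hits: dict[str, set[int]] = {}
    for row, seq in enumerate(sequences):
        for i in range(len(seq) - k + 1):
            kmer = seq[i: i + k]
            hits.setdefault(collapse_kmer(kmer), set()).add(row)
    return {k_: np.fromiter(v, dtype=np.int64) for k_, v in hits.items()}


def escore_table(probes: pd.DataFrame) -> EscoreTable:
    """E-scores for every reverse-complement-collapsed 8-mer present in >= 1 probe.

    Equivalent to calling :func:`escore` per 8-mer, but shares one global
    intensity ordering across all 8-mers so the full table is tractable.
    """
    df = _clean_probes(probes)
    if (df["sequence"].str.len() < 8).any():
        raise ValueError("probe sequences must be at least 8 nt")
    intensity = df["intensity"].to_numpy(float)
    n = len(df)
    index = _kmer_index(df["sequence"])

    desc = np.argsort(-intensity, kind="stable")  # probe rows, brightest first
    pos_of_row = np.empty(n, dtype=np.int64)
    pos_of_row[desc] = np.arange(n)
    intensity_desc = intensity[desc]

    kmers = sorted(index)
    scores = np.full(len(kmers), np.nan)
    n_fg = np.zeros(len(kmers), dtype=np.int64)
    for j, kmer in enumerate(kmers):
        rows = index[kmer]
        f = len(rows)
        n_fg[j] = f
        nb = n - f
        if f == 0 or nb == 0:
            continue
        fg = _half_top(intensity[rows])
        nb_top = math.ceil(nb / 2)
        # brightest nb_top background probes: the first nb_top entries of the
        # global descending order once foreground positions are masked out --
        # those all sit within the first nb_top + f positions
        limit = nb_top + f
        mask = np.zeros(limit, dtype=bool)
        fg_pos = pos_of_row[rows]
        mask[fg_pos[fg_pos < limit]] = True
        bg = intensity_desc[:limit][~mask][:nb_top]
        scores[j] = _pair_u(fg, bg) / (len(fg) * len(bg)) - 0.5
    return EscoreTable(
        pd.Series(scores, index=kmers), pd.Series(n_fg, index=kmers)
    )


def compare_landscapes(
    wt: EscoreTable, var: EscoreTable, cutoff: float = SIGNIFICANCE_CUTOFF
) -> dict:
    """Compare two 8-mer E-score landscapes from the same probe design.

    Returns significant-8-mer counts per allele, per-class proportions of
    the significant 8-mers, shared/unique significant sets, and (E_wt,
    E_var) scatter pairs over shared keys.
    """
    shared_keys = wt.scores.index.intersection(var.scores.index)
    if len(shared_keys) == 0:
        raise ValueError("E-score tables share no 8-mers: probe design mismatch")
    sig_wt = wt.significant(cutoff)
    sig_var = var.significant(cutoff)

    def class_proportions(kmers: set[str]) -> dict[str, float]:
        if not kmers:
            return {}
        counts: dict[str, int] = {}
        for k in kmers:
            cls = assign_motif_class(k)
            counts[cls] = counts.get(cls, 0) + 1
        return {c: v / len(kmers) for c, v in sorted(counts.items())}

    return {
        "cutoff": cutoff,
        "n_significant_wt": len(sig_wt),
        "n_significant_var": len(sig_var),
        "shared_significant": sorted(sig_wt & sig_var),
        "wt_only_significant": sorted(sig_wt - sig_var),
        "var_only_significant": sorted(sig_var - sig_wt),
        "class_proportions_wt": class_proportions(sig_wt),
        "class_proportions_var": class_proportions(sig_var),
        "scatter": pd.DataFrame(
            {"e_wt": wt.scores[shared_keys], "e_var": var.scores[shared_keys]}
        ),
    }


def write_comparison_summary(summary: dict, path: str | Path) -> None:
    out = {k: v for k, v in summary.items() if k != "scatter"}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"probe_id", "sequence", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"probe table needs columns {sorted(required)}")
    return df


def write_probe_table(probes: pd.DataFrame, path: str | Path) -> None:
    probes[["probe_id", "sequence", "intensity"]].to_csv(path, index=False)


def all_collapsed_8mers() -> list[str]:
    """All 32,896 reverse-complement-collapsed 8-mers, sorted."""
    out = set()
    for tup in itertools.product("ACGT", repeat=8):
        out.add(collapse_kmer("".join(tup)))
    return sorted(out)
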