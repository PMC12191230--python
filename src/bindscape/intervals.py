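"""Genomic interval primitives and BED I/O.

Coordinates are 0-based half-open throughout, matching BED. Peak sets are
kept sorted by (chrom, start) with overlapping and bookended (adjacent)
intervals merged, so that all downstream set arithmetic operates on
disjoint intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = ["GenomicInterval", "PeakSet", "read_bed", "write_bed"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _merge_sorted(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and bookended intervals; input must be sorted."""
    merged: list[GenomicInterval] = []
    for iv in intervals:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(
                    prev.chrom, prev.start, iv.end, name=prev.name, score=prev.score
                )
        else:
            merged.append(iv)
    return merged


class PeakSet:
    """An allele-labelled set of disjoint, sorted genomic intervals."""

    def __init__(
        self,
        allele: str,
        intervals: Iterable[GenomicInterval],
        merge: bool = True,
    ) -> None:
        self.allele = allele
        ivs = sorted(intervals)
        self.intervals: list[GenomicInterval] = _merge_sorted(ivs) if merge else ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.allele == other.allele and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(allele={self.allele!r}, n={len(self)}, bp={self.total_bp})"

    @property
    def total_bp(self) -> int:
        return sum(iv.width for iv in self.intervals)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) array of [start, end) pairs."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.array(v, dtype=np.int64) for c, v in out.items()}

    def to_bed(self, path: str | Path) -> None:
        write_bed(self.intervals, path)

    @classmethod
    def from_bed(cls, path: str | Path, allele: str, merge: bool = True) -> "PeakSet":
        return cls(allele, read_bed(path), merge=merge)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name, score)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")
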