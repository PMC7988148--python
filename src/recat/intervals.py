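"""Genomic coordinate types and interval algebra.

All coordinates are 0-based half-open (BED convention).  GFF3 input is
converted at the boundary by :mod:`recat.io`.  Regulatory elements are
unstranded; strand appears only on reads, genes and motif hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SegmentationRecord",
    "ReadRecord",
    "overlap_bp",
    "merge_intervals",
    "IntervalIndex",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2

    def contains(self, pos: int) -> bool:
        """Half-open containment of a single base position."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_bp(self, other) > 0

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene with one TSS per annotated transcript.

    ``tss_list`` holds 0-based TSS positions: the start of a ``+`` strand
    transcript, or ``end - 1`` of a ``-`` strand transcript.
    """

    gene_id: str
    biotype: str  # "protein_coding" | "non_coding"
    body: GenomicInterval
    strand: str  # "+" | "-"
    tss_list: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for tss in self.tss_list:
            if not self.body.contains(tss):
                raise ValueError(
                    f"TSS {tss} outside gene body {self.body} ({self.gene_id})"
                )

    @property
    def tss_5prime(self) -> int:
        """The 5'-most TSS: smallest on ``+`` genes, largest on ``-`` genes."""
        return min(self.tss_list) if self.strand == "+" else max(self.tss_list)


@dataclass(frozen=True)
class SegmentationRecord:
    """One chromatin-state segment of a per-tissue dense segmentation."""

    interval: GenomicInterval
    state: int
    tissue: str

    def __post_init__(self) -> None:
        if not 1 <= self.state <= 14:
            raise ValueError(f"chromatin state out of range 1..14: {self.state}")


@dataclass(frozen=True)
class ReadRecord:
    """A mapped read reduced to its genomic interval and strand."""

    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    intervals: Iterable[GenomicInterval], bookended: bool = True
) -> list[GenomicInterval]:
    """Collapse intervals into the minimal sorted set of disjoint intervals.

    With ``bookended=True`` (BEDTools-merge default), abutting intervals
    (``a.end == b.start``) are joined as well; otherwise only intervals
    sharing at least one base are joined.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        joins = (
            iv.chrom == cur_chrom
            and (iv.start < cur_end or (bookended and iv.start == cur_end))
        )
        if joins:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


@dataclass
class IntervalIndex:
    """Sorted per-chromosome index over *disjoint* intervals.

    Input intervals are merged (overlap-only, not bookended) on
    construction, so point and overlap queries run in O(log n) with plain
    binary searches.  Suitable wherever only coverage matters (peaks,
    catalogs, TADs) -- not for stabbing queries against overlapping gene
    bodies.
    """

    intervals: Sequence[GenomicInterval]
    _starts: dict[str, np.ndarray] = field(init=False, repr=False)
    _ends: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        merged = merge_intervals(self.intervals, bookended=False)
        self.intervals = merged
        self._starts, self._ends = {}, {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def contains_point(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < self._ends[chrom][i]

    def any_overlap(self, iv: GenomicInterval) -> bool:
        return self.overlap_bp(iv) > 0

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Total bases of ``iv`` covered by the indexed intervals."""
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return 0
        ends = self._ends[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        total = 0
        for i in range(lo, hi):
            total += max(0, min(int(ends[i]), iv.end) - max(int(starts[i]), iv.start))
        return total

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized half-open point containment for one chromosome."""
        starts = self._starts.get(chrom)
        if starts is None:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(positions), dtype=bool)
        res[ok] = positions[ok] < self._ends[chrom][idx[ok]]
        return res

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)
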