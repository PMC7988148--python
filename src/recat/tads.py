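"""TAD prediction from CTCF peaks via motif orientation.

Peaks pooled across tissues are scanned for the CTCF motif; each retained
peak contributes one oriented site (its best-scoring hit).  A forward site
pairs with the nearest downstream reverse site within ``max_span``
(convergent loop-extrusion logic); nested and overlapping loops are merged
into disjoint TADs.  Bookended loops are NOT merged: two domains sharing a
boundary stay distinct.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import GenomicInterval, merge_intervals, overlap_bp
from .motif import MotifHit, Pwm, scan_sequence

__all__ = [
    "OrientedSite",
    "Tad",
    "orient_peaks",
    "pair_loops",
    "merge_loops",
    "tad_coverage",
    "predict_tads",
]

DEFAULT_MAX_SPAN = 1_000_000  # bp


@dataclass(frozen=True)
class OrientedSite:
    chrom: str
    position: int  # motif midpoint
    orientation: str  # "forward" | "reverse"
    source_peak: str

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class Tad:
    interval: GenomicInterval


def orient_peaks(
    peaks: Sequence[GenomicInterval], hits: Sequence[MotifHit]
) -> list[OrientedSite]:
    """One oriented site per peak holding a motif hit.

    The single best-scoring hit within the peak wins (ties broken by
    smaller start, then ``+`` strand); peaks without any hit are dropped.
    The site position is the hit midpoint.
    """
    hits_sorted = sorted(hits, key=lambda h: (h.interval.chrom, h.interval.start))
    sites: list[OrientedSite] = []
    for i, peak in enumerate(sorted(peaks)):
        best: MotifHit | None = None
        for h in hits_sorted:
            if h.interval.chrom != peak.chrom:
                continue
            if overlap_bp(h.interval, peak) == 0:
                continue
            if best is None:
                best = h
                continue
            better = h.score > best.score or (
                h.score == best.score
                and (
                    h.interval.start < best.interval.start
                    or (h.interval.start == best.interval.start and h.strand == "+")
                )
            )
            if better:
                best = h
        if best is not None:
            sites.append(
                OrientedSite(
                    chrom=peak.chrom,
                    position=best.interval.midpoint,
                    orientation="forward" if best.strand == "+" else "reverse",
                    source_peak=f"peak{i}",
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.position))
    return sites


def pair_loops(
    sites: Sequence[OrientedSite], max_span: int = DEFAULT_MAX_SPAN
) -> list[GenomicInterval]:
    """Convergent pairing: each forward site with its nearest downstream
    reverse site within ``max_span``; unpaired forward sites emit nothing."""
    loops: list[GenomicInterval] = []
    by_chrom: dict[str, list[OrientedSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        ss = sorted(by_chrom[chrom], key=lambda s: s.position)
        rev_positions = [s.position for s in ss if s.orientation == "reverse"]
        for s in ss:
            if s.orientation != "forward":
                continue
            j = bisect.bisect_right(rev_positions, s.position)
            if j < len(rev_positions) and rev_positions[j] - s.position <= max_span:
                loops.append(GenomicInterval(chrom, s.position, rev_positions[j]))
    return loops


def merge_loops(loops: Sequence[GenomicInterval]) -> list[Tad]:
    """Transitive union of overlapping/nested loops (bookended NOT merged)."""
    return [Tad(iv) for iv in merge_intervals(loops, bookended=False)]


def tad_coverage(tads: Sequence[Tad], genome_size: int) -> float:
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return sum(t.interval.length for t in tads) / genome_size


def predict_tads(
    genome: Mapping[str, str],
    peaks: Sequence[GenomicInterval],
    pwm: Pwm,
    pvalue_threshold: float = 1e-4,
    max_span: int = DEFAULT_MAX_SPAN,
) -> tuple[list[Tad], list[OrientedSite]]:
    """Full stage: scan peak sequence, orient peaks, pair and merge loops.

    Only the peak spans (not the whole genome) need scanning, since sites
    are defined by hits within peaks.
    """
    hits: list[MotifHit] = []
    for peak in sorted(peaks):
        seq = genome[peak.chrom][peak.start : peak.end]
        for h in scan_sequence(seq, pwm, pvalue_threshold, chrom=peak.chrom):
            hits.append(
                MotifHit(
                    GenomicInterval(
                        peak.chrom,
                        h.interval.start + peak.start,
                        h.interval.end + peak.start,
                    ),
                    h.strand,
                    h.score,
                )
            )
    sites = orient_peaks(peaks, hits)
    tads = merge_loops(pair_loops(sites, max_span=max_span))
    return tads, sites
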