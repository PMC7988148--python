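"""ChIP-seq library quality metrics on mapped-read interval tables.

NRF and the PCR bottleneck coefficients use the ENCODE duplicate
definition: a "location" is the full (chrom, start, end, strand) tuple.
JSD bins read starts into fixed windows and is the Jensen-Shannon
*distance* (square root of the log2-based divergence) between the ChIP and
input binned distributions; raw coverage is used, not input-subtracted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .intervals import GenomicInterval, IntervalIndex, ReadRecord

__all__ = ["QcReport", "nrf", "pbc1_pbc2", "frip", "jsd", "qc_report"]


@dataclass(frozen=True)
class QcReport:
    nrf: float
    pbc1: float
    pbc2: float
    frip: float
    jsd: float
    thresholds_passed: dict[str, bool]


def _location_counts(reads: Sequence[ReadRecord]) -> Counter:
    if not reads:
        raise ValueError("empty read list")
    return Counter(
        (r.interval.chrom, r.interval.start, r.interval.end, r.strand) for r in reads
    )


def nrf(reads: Sequence[ReadRecord]) -> float:
    """Non-redundant fraction: distinct locations / total reads."""
    counts = _location_counts(reads)
    return len(counts) / len(reads)


def pbc1_pbc2(reads: Sequence[ReadRecord]) -> tuple[float, float]:
    """PCR bottleneck coefficients.

    PBC1 = N1 / Nd (locations with exactly one read over locations with any
    read); PBC2 = N1 / N2.  With no doubly-hit location PBC2 is reported as
    +inf.
    """
    counts = _location_counts(reads)
    n1 = sum(1 for c in counts.values() if c == 1)
    n2 = sum(1 for c in counts.values() if c == 2)
    pbc1 = n1 / len(counts)
    pbc2 = n1 / n2 if n2 > 0 else float("inf")
    return (pbc1, pbc2)


def frip(reads: Sequence[ReadRecord], peaks: Sequence[GenomicInterval]) -> float:
    """Fraction of reads overlapping any peak by >= 1 bp."""
    if not reads:
        raise ValueError("empty read list")
    if not peaks:
        return 0.0
    index = IntervalIndex(peaks)
    hit = sum(1 for r in reads if index.any_overlap(r.interval))
    return hit / len(reads)


def _bin_counts(reads: Sequence[ReadRecord], bin_size: int) -> Counter:
    counts: Counter = Counter()
    for r in reads:
        counts[(r.interval.chrom, r.interval.start // bin_size)] += 1
    return counts


def jsd(
    chip_reads: Sequence[ReadRecord],
    input_reads: Sequence[ReadRecord],
    bin_size: int = 500,
) -> float:
    """Jensen-Shannon distance between binned read-start distributions.

    Bins with at least one read in either library form the support; each
    library is normalized to a probability vector over that support.
    Returns sqrt(JS divergence) with log base 2, so the value lies in
    [0, 1].
    """
    if not chip_reads or not input_reads:
        raise ValueError("both libraries must be non-empty")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    c = _bin_counts(chip_reads, bin_size)
    i = _bin_counts(input_reads, bin_size)
    support = sorted(set(c) | set(i))
    p = np.array([c.get(b, 0) for b in support], dtype=float)
    q = np.array([i.get(b, 0) for b in support], dtype=float)
    d = float(jensenshannon(p, q, base=2))
    # guard scipy's occasional tiny negative under the sqrt
    return min(1.0, max(0.0, d))


def qc_report(
    chip_reads: Sequence[ReadRecord],
    input_reads: Sequence[ReadRecord],
    peaks: Sequence[GenomicInterval],
    bin_size: int = 500,
) -> QcReport:
    """Compute all metrics plus ENCODE-style qualitative flags."""
    v_nrf = nrf(chip_reads)
    v_pbc1, v_pbc2 = pbc1_pbc2(chip_reads)
    v_frip = frip(chip_reads, peaks)
    v_jsd = jsd(chip_reads, input_reads, bin_size=bin_size)
    flags = {
        # 0.5-0.8 is the "acceptable" NRF band; above it is better
        "nrf_acceptable": v_nrf >= 0.5,
        "pbc1_acceptable": v_pbc1 >= 0.5,
        # 3-10 is "mild bottlenecking"; >= 10 indicates little bottlenecking
        "pbc2_acceptable": v_pbc2 >= 3.0,
    }
    return QcReport(v_nrf, v_pbc1, v_pbc2, v_frip, v_jsd, flags)
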