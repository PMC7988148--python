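"""Position-weight matrices and FIMO-style log-odds scanning.

Scores are ``sum_j log2(p'_j(base) / 0.25)`` where ``p'`` is the PWM row
after adding pseudocount 1e-3 and renormalizing.  The score threshold for a
requested p-value is computed exactly by dynamic programming over the
discretized score distribution under the uniform-background null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval

__all__ = ["Pwm", "MotifHit", "score_threshold", "scan_pwm", "scan_sequence"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PSEUDOCOUNT = 1e-3
GRANULARITY = 1e-3  # bits; discretization step of the null-score DP


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Pwm:
    """Per-position base probabilities over A, C, G, T (rows sum to 1)."""

    probs: np.ndarray  # shape (length, 4)
    name: str = "motif"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("PWM must be a (length, 4) matrix")
        if (probs < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 within 1e-9")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(length, 4) log2 odds vs uniform background, after pseudocount."""
        p = (self.probs + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT)
        return np.log2(p / 0.25)

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.probs[::-1, ::-1].copy(), name=self.name)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not np.isfinite(self.score):
            raise ValueError("hit score must be finite")


def score_threshold(pwm: Pwm, pvalue: float, granularity: float = GRANULARITY) -> float:
    """Smallest score s with ``P(S >= s) <= pvalue`` under uniform background.

    The null score distribution is computed by exact dynamic programming
    over scores discretized to ``granularity`` bits (each position
    contributes one of its four column scores with probability 1/4).
    """
    if not 0.0 < pvalue < 1.0:
        raise ValueError("pvalue threshold must lie in (0, 1)")
    lo = pwm.log_odds()
    scaled = np.rint(lo / granularity).astype(np.int64)  # (L, 4)
    offset = scaled.min(axis=1).sum()
    span = int((scaled.max(axis=1) - scaled.min(axis=1)).sum()) + 1
    dist = np.zeros(span, dtype=float)
    dist[0] = 1.0
    width = 1
    for row in scaled:
        row = row - row.min()
        new_width = width + int(row.max())
        new = np.zeros(new_width, dtype=float)
        for s in row:
            new[s : s + width] += dist[:width]
        new *= 0.25
        dist[:new_width] = new
        width = new_width
    tail = np.cumsum(dist[:width][::-1])[::-1]
    idx = np.nonzero(tail <= pvalue)[0]
    if len(idx) == 0:
        # even the maximal score is more probable than requested: only the
        # top of the support qualifies
        i = width - 1
    else:
        i = int(idx[0])
    return (i + offset) * granularity


_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score of every window start; windows containing N get -inf."""
    L = lo.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=float)
    # append a -inf column for N so any window touching N is excluded
    cols = np.column_stack([lo, np.full(L, -np.inf)])
    scores = np.zeros(n_win, dtype=float)
    for j in range(L):
        scores += cols[j, codes[j : j + n_win]]
    return scores


def scan_sequence(
    seq: str, pwm: Pwm, pvalue_threshold: float = 1e-4, chrom: str = "seq"
) -> list[MotifHit]:
    """Scan one sequence on both strands, reporting hits at or above the
    score threshold implied by ``pvalue_threshold``."""
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)!r}")
    thresh = score_threshold(pwm, pvalue_threshold)
    codes = _encode(seq)
    hits: list[MotifHit] = []
    fwd = _window_scores(codes, pwm.log_odds())
    rev = _window_scores(codes, pwm.reverse_complement().log_odds())
    L = pwm.length
    for strand, scores in (("+", fwd), ("-", rev)):
        for i in np.nonzero(scores >= thresh - 1e-12)[0]:
            hits.append(
                MotifHit(GenomicInterval(chrom, int(i), int(i) + L), strand, float(scores[i]))
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_pwm(
    genome: dict[str, str], pwm: Pwm, pvalue_threshold: float = 1e-4
) -> list[MotifHit]:
    """Scan every chromosome of a genome dict (name -> sequence)."""
    hits: list[MotifHit] = []
    for chrom in sorted(genome):
        hits.extend(scan_sequence(genome[chrom], pwm, pvalue_threshold, chrom=chrom))
    return hits
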