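"""Consolidation of per-tissue chromatin-state segmentations into a
regulatory-element (RE) catalog.

Active states (by default 1-6, 8, 9 and 11 of a 14-state model) are merged
into maximal per-tissue active runs, combined across tissues with
bookended merging, annotated with the contributing tissues, and classified
relative to gene annotations:

* ``tss_proximal`` -- within 2 kb (inclusive) of a protein-coding TSS;
* ``excluded``     -- else within 2 kb of a non-coding or unannotated TSS;
* ``genic``        -- else overlapping a gene body by >= 1 bp;
* ``intergenic``   -- otherwise.

Protein-coding proximity deliberately takes precedence over exclusion: the
exclusion rule exists to avoid calling promoters of non-coding transcripts
"enhancers", which cannot apply to an RE already sitting at a coding TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    SegmentationRecord,
    merge_intervals,
    overlap_bp,
)

__all__ = [
    "ACTIVE_STATES",
    "TSS_WINDOW",
    "RegulatoryElement",
    "consolidate_active",
    "combine_tissues",
    "classify_re",
    "classify_catalog",
    "open_chromatin_support",
    "state_feature_enrichment",
    "build_catalog",
]

ACTIVE_STATES = frozenset({1, 2, 3, 4, 5, 6, 8, 9, 11})
TSS_WINDOW = 2_000  # bp, inclusive distance defining TSS proximity


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    active_tissues: frozenset[str]
    re_class: str | None = None  # tss_proximal | genic | intergenic | excluded

    def __post_init__(self) -> None:
        if not self.active_tissues:
            raise ValueError(f"RE {self.interval} has no active tissues")
        if self.re_class is not None and self.re_class not in (
            "tss_proximal",
            "genic",
            "intergenic",
            "excluded",
        ):
            raise ValueError(f"unknown RE class {self.re_class!r}")

    @property
    def tissue_specific(self) -> bool:
        return len(self.active_tissues) == 1


def consolidate_active(
    records: Sequence[SegmentationRecord],
    active_states: frozenset[int] = ACTIVE_STATES,
) -> list[GenomicInterval]:
    """Merge consecutive/abutting active-state segments of ONE tissue.

    Records must be non-overlapping within a chromosome; abutting active
    segments merge into a single maximal run (bookended merge).
    """
    recs = sorted(records, key=lambda r: r.interval)
    prev = None
    for r in recs:
        if (
            prev is not None
            and r.interval.chrom == prev.interval.chrom
            and r.interval.start < prev.interval.end
        ):
            raise ValueError(f"overlapping segments within one tissue at {r.interval}")
        prev = r
    active = [r.interval for r in recs if r.state in active_states]
    return merge_intervals(active, bookended=True)


def combine_tissues(
    per_tissue: Mapping[str, Sequence[GenomicInterval]],
) -> list[RegulatoryElement]:
    """Union-merge per-tissue active intervals across tissues.

    Bookended merging is on (BEDTools default).  Each combined RE is
    annotated with every tissue contributing at least one base.
    """
    all_ivs = [iv for ivs in per_tissue.values() for iv in ivs]
    merged = merge_intervals(all_ivs, bookended=True)
    indexes = {t: IntervalIndex(ivs) for t, ivs in per_tissue.items() if ivs}
    res = []
    for iv in merged:
        tissues = frozenset(t for t, idx in indexes.items() if idx.any_overlap(iv))
        res.append(RegulatoryElement(iv, tissues))
    return res


def _near_tss(iv: GenomicInterval, chrom: str, tss: int, window: int) -> bool:
    """True when iv comes within ``window`` bp (inclusive) of the TSS base."""
    if iv.chrom != chrom:
        return False
    return iv.start <= tss + window and iv.end > tss - window


def classify_re(
    re_interval: GenomicInterval,
    genes: Sequence[GeneModel],
    extra_tss: Sequence[tuple[str, int]] = (),
    window: int = TSS_WINDOW,
) -> str:
    """Assign one class by precedence (see module docstring)."""
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        for tss in g.tss_list:
            if _near_tss(re_interval, g.body.chrom, tss, window):
                return "tss_proximal"
    for g in genes:
        if g.biotype == "protein_coding":
            continue
        for tss in g.tss_list:
            if _near_tss(re_interval, g.body.chrom, tss, window):
                return "excluded"
    for chrom, tss in extra_tss:
        if _near_tss(re_interval, chrom, tss, window):
            return "excluded"
    for g in genes:
        if overlap_bp(re_interval, g.body) > 0:
            return "genic"
    return "intergenic"


def classify_catalog(
    res: Sequence[RegulatoryElement],
    genes: Sequence[GeneModel],
    extra_tss: Sequence[tuple[str, int]] = (),
    window: int = TSS_WINDOW,
) -> list[RegulatoryElement]:
    """Classify every RE of a catalog (scales by bucketing genes per chromosome)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    tss_by_chrom: dict[str, list[tuple[str, int]]] = {}
    for chrom, tss in extra_tss:
        tss_by_chrom.setdefault(chrom, []).append((chrom, tss))
    out = []
    for re in res:
        cls = classify_re(
            re.interval,
            by_chrom.get(re.interval.chrom, ()),
            tss_by_chrom.get(re.interval.chrom, ()),
            window=window,
        )
        out.append(RegulatoryElement(re.interval, re.active_tissues, cls))
    return out


def open_chromatin_support(
    res: Sequence[RegulatoryElement],
    accessibility_peaks: Mapping[str, Sequence[GenomicInterval]],
) -> tuple[float, list[bool]]:
    """Fraction of REs overlapping an accessibility peak in >=1 active tissue.

    The overlap must come from a tissue in the RE's own activity set
    (tissue-matched co-occurrence).
    """
    indexes = {t: IntervalIndex(p) for t, p in accessibility_peaks.items() if p}
    flags = []
    for re in res:
        supported = any(
            t in indexes and indexes[t].any_overlap(re.interval)
            for t in re.active_tissues
        )
        flags.append(supported)
    frac = sum(flags) / len(flags) if flags else 0.0
    return frac, flags


def state_feature_enrichment(
    records: Sequence[SegmentationRecord],
    features: Sequence[GenomicInterval],
    genome_size: int,
) -> dict[int, float]:
    """Per-state fold enrichment of overlap with a feature set.

    ``(bp of state in features / bp of state) / (feature bp / genome bp)``.
    States absent from the segmentation map to NaN.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    feature_index = IntervalIndex(features)
    feature_bp = feature_index.total_bp
    state_bp: dict[int, int] = {s: 0 for s in range(1, 15)}
    state_hit: dict[int, int] = {s: 0 for s in range(1, 15)}
    for r in records:
        state_bp[r.state] += r.interval.length
        state_hit[r.state] += feature_index.overlap_bp(r.interval)
    background = feature_bp / genome_size
    out: dict[int, float] = {}
    for s in range(1, 15):
        if state_bp[s] == 0 or background == 0:
            out[s] = float("nan")
        else:
            out[s] = (state_hit[s] / state_bp[s]) / background
    return out


def build_catalog(
    segmentations: Mapping[str, Sequence[SegmentationRecord]],
    genes: Sequence[GeneModel],
    extra_tss: Sequence[tuple[str, int]] = (),
    active_states: frozenset[int] = ACTIVE_STATES,
) -> list[RegulatoryElement]:
    """Full annotation stage: consolidate, combine, classify."""
    per_tissue = {
        tissue: consolidate_active(recs, active_states)
        for tissue, recs in segmentations.items()
    }
    catalog = combine_tissues(per_tissue)
    return classify_catalog(catalog, genes, extra_tss)


def catalog_to_bed_records(res: Sequence[RegulatoryElement]):
    """Catalog as BED6+ records: name=RE id, extra = class, tissue list."""
    from .io import BedRecord

    recs = []
    for i, re in enumerate(sorted(res, key=lambda r: r.interval)):
        recs.append(
            BedRecord(
                re.interval,
                name=f"RE{i:06d}",
                score=0.0,
                strand=None,
                extra=(re.re_class or ".", ",".join(sorted(re.active_tissues))),
            )
        )
    return recs


def catalog_from_bed_records(records) -> list[RegulatoryElement]:
    res = []
    for rec in records:
        if len(rec.extra) < 2:
            raise ValueError("catalog BED needs class and tissue columns")
        cls = rec.extra[0] if rec.extra[0] != "." else None
        tissues = frozenset(t for t in rec.extra[1].split(",") if t)
        res.append(RegulatoryElement(rec.interval, tissues, cls))
    return res
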