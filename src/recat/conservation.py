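"""Cross-species RE mapping over gapless alignment blocks and
conservation calling.

An alignment-block map is an ordered set of equal-length source/target
interval pairs (source intervals pairwise disjoint).  An interval maps by
collecting the target positions of all of its aligned bases; if they
scatter over several target chromosomes, the chromosome receiving the most
bases wins (ties: lexicographically smallest name) and the mapped interval
is the min..max span of its positions.  A mapped RE is conserved when its
mapped span overlaps a target-species RE by at least 1 bp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, IntervalIndex

__all__ = [
    "AlignmentBlock",
    "AlignmentBlockMap",
    "map_interval",
    "call_conservation",
    "lineage_conserved",
    "ConservationResult",
    "read_block_map",
    "write_block_map",
]


@dataclass(frozen=True)
class AlignmentBlock:
    src: GenomicInterval
    tgt: GenomicInterval
    tgt_strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.src.length != self.tgt.length:
            raise ValueError(f"block is not gapless: {self.src} vs {self.tgt}")
        if self.tgt_strand not in ("+", "-"):
            raise ValueError(f"bad target strand {self.tgt_strand!r}")


@dataclass
class AlignmentBlockMap:
    blocks: list[AlignmentBlock]
    src_species: str = "source"
    tgt_species: str = "target"

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b.src)
        prev: AlignmentBlock | None = None
        for b in self.blocks:
            if (
                prev is not None
                and b.src.chrom == prev.src.chrom
                and b.src.start < prev.src.end
            ):
                raise ValueError(f"overlapping source blocks at {b.src}")
            prev = b

    def inverse(self) -> "AlignmentBlockMap":
        """Map with source and target swapped (strand semantics preserved)."""
        inv = [AlignmentBlock(b.tgt, b.src, b.tgt_strand) for b in self.blocks]
        return AlignmentBlockMap(inv, self.tgt_species, self.src_species)


@dataclass(frozen=True)
class ConservationResult:
    re_id: str
    mapped: bool
    mapped_interval: GenomicInterval | None
    conserved: bool

    def __post_init__(self) -> None:
        if self.conserved and not self.mapped:
            raise ValueError("conserved implies mapped")


def map_interval(
    iv: GenomicInterval, block_map: AlignmentBlockMap
) -> GenomicInterval | None:
    """Map an interval through the block map; None when no base aligns.

    Within a ``-`` strand block, positions are mirrored inside the block
    before the overall min/max span is taken.
    """
    spans: dict[str, list[tuple[int, int]]] = {}  # chrom -> (start, end) pieces
    bases: dict[str, int] = {}
    for b in block_map.blocks:
        if b.src.chrom != iv.chrom:
            continue
        lo = max(b.src.start, iv.start)
        hi = min(b.src.end, iv.end)
        if lo >= hi:
            continue
        if b.tgt_strand == "+":
            t_lo = b.tgt.start + (lo - b.src.start)
            t_hi = b.tgt.start + (hi - b.src.start)
        else:
            t_hi = b.tgt.end - (lo - b.src.start)
            t_lo = b.tgt.end - (hi - b.src.start)
        spans.setdefault(b.tgt.chrom, []).append((t_lo, t_hi))
        bases[b.tgt.chrom] = bases.get(b.tgt.chrom, 0) + (hi - lo)
    if not spans:
        return None
    # majority-base rule with lexicographic tie-break
    best = sorted(bases, key=lambda c: (-bases[c], c))[0]
    lo = min(s for s, _ in spans[best])
    hi = max(e for _, e in spans[best])
    return GenomicInterval(best, lo, hi)


def call_conservation(
    re_intervals: Mapping[str, GenomicInterval],
    block_map: AlignmentBlockMap,
    target_res: Sequence[GenomicInterval],
    min_mapped_frac: float = 0.0,
) -> tuple[list[ConservationResult], float, float]:
    """Map every source RE and call conservation against the target catalog.

    Returns (per-RE results, mapping_rate, conservation_rate) where
    mapping_rate = mapped/total and conservation_rate = conserved/mapped.
    ``min_mapped_frac`` optionally requires that fraction of the source
    bases to be aligned for the RE to count as mapped (default 0: >=1 bp).
    """
    target_index = IntervalIndex(target_res)
    src_index_bp = _aligned_bp_index(block_map)
    results: list[ConservationResult] = []
    for re_id in sorted(re_intervals):
        iv = re_intervals[re_id]
        mapped_iv = map_interval(iv, block_map)
        mapped = mapped_iv is not None
        if mapped and min_mapped_frac > 0:
            aligned = src_index_bp.overlap_bp(iv)
            if aligned < min_mapped_frac * iv.length:
                mapped, mapped_iv = False, None
        conserved = bool(mapped_iv is not None and target_index.any_overlap(mapped_iv))
        results.append(ConservationResult(re_id, mapped, mapped_iv, conserved))
    n = len(results)
    n_mapped = sum(r.mapped for r in results)
    n_cons = sum(r.conserved for r in results)
    mapping_rate = n_mapped / n if n else float("nan")
    conservation_rate = n_cons / n_mapped if n_mapped else float("nan")
    return results, mapping_rate, conservation_rate


def _aligned_bp_index(block_map: AlignmentBlockMap) -> IntervalIndex:
    return IntervalIndex([b.src for b in block_map.blocks])


def lineage_conserved(
    per_target: Mapping[str, Iterable[ConservationResult]],
    species_set: Iterable[str],
) -> set[str]:
    """Source RE ids conserved against every target species in the set."""
    species = list(species_set)
    missing = [s for s in species if s not in per_target]
    if missing:
        raise KeyError(f"no conservation results for species: {missing}")
    sets = [
        {r.re_id for r in per_target[s] if r.conserved} for s in species
    ]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


# ---------------------------------------------------------------------------
# Block map TSV: src_chrom src_start src_end tgt_chrom tgt_start tgt_end tgt_strand
# ---------------------------------------------------------------------------


def read_block_map(
    path: str | os.PathLike, src_species: str = "source", tgt_species: str = "target"
) -> AlignmentBlockMap:
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            sc, ss, se, tc, ts, te, strand = fields
            blocks.append(
                AlignmentBlock(
                    GenomicInterval(sc, int(ss), int(se)),
                    GenomicInterval(tc, int(ts), int(te)),
                    strand,
                )
            )
    return AlignmentBlockMap(blocks, src_species, tgt_species)


def write_block_map(path: str | os.PathLike, block_map: AlignmentBlockMap) -> None:
    with open(path, "w") as fh:
        fh.write("#src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\ttgt_end\ttgt_strand\n")
        for b in block_map.blocks:
            fh.write(
                "\t".join(
                    [
                        b.src.chrom, str(b.src.start), str(b.src.end),
                        b.tgt.chrom, str(b.tgt.start), str(b.tgt.end), b.tgt_strand,
                    ]
                )
                + "\n"
            )
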