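"""Readers and writers for every on-disk format the pipeline touches.

Formats: BED3/BED6 (tab-separated, 0-based half-open), GFF3 (1-based
inclusive, converted here), FASTA, TSV count matrices (header row = sample
ids, first column = feature ids), minimal MEME motifs, alignment-block TSV,
catalog BED6+ and SNP TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, ReadRecord, SegmentationRecord

__all__ = [
    "BedRecord",
    "read_bed",
    "write_bed",
    "read_intervals",
    "read_reads",
    "write_reads",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_matrix",
    "write_matrix",
    "read_fasta",
    "write_fasta",
    "read_meme_pwm",
    "write_meme_pwm",
    "read_segmentation",
    "write_segmentation",
]


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str | None = None
    score: float | None = None
    strand: str | None = None
    extra: tuple[str, ...] = ()


def _check_coords(chrom: str, start_s: str, end_s: str, path, lineno: int) -> GenomicInterval:
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0:
        raise ParseError(f"{path}:{lineno}: negative start coordinate {start}")
    if end <= start:
        raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
    return GenomicInterval(chrom, start, end)


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    """Read BED3/BED6(+) records; coordinates are kept 0-based half-open."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            iv = _check_coords(fields[0], fields[1], fields[2], path, lineno)
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            strand = None
            if len(fields) > 5 and fields[5] != ".":
                if fields[5] not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: bad strand {fields[5]!r}")
                strand = fields[5]
            records.append(BedRecord(iv, name, score, strand, tuple(fields[6:])))
    return records


def write_bed(path: str | os.PathLike, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fields = [rec.interval.chrom, str(rec.interval.start), str(rec.interval.end)]
            has_later = rec.score is not None or rec.strand is not None or rec.extra
            if rec.name is not None or has_later:
                fields.append(rec.name if rec.name is not None else ".")
            if rec.score is not None or rec.strand is not None or rec.extra:
                fields.append(f"{rec.score:g}" if rec.score is not None else ".")
            if rec.strand is not None or rec.extra:
                fields.append(rec.strand if rec.strand is not None else ".")
            fields.extend(rec.extra)
            fh.write("\t".join(fields) + "\n")


def read_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    return [rec.interval for rec in read_bed(path)]


def read_reads(path: str | os.PathLike) -> list[ReadRecord]:
    """Read a mapped-read interval table (BED6; strand required)."""
    reads = []
    for i, rec in enumerate(read_bed(path), start=1):
        if rec.strand is None:
            raise ParseError(f"{path}: record {i} lacks a strand")
        reads.append(ReadRecord(rec.interval, rec.strand))
    return reads


def write_reads(path: str | os.PathLike, reads: Iterable[ReadRecord]) -> None:
    write_bed(
        path,
        (BedRecord(r.interval, name=".", score=0.0, strand=r.strand) for r in reads),
    )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def _gff3_attrs(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from GFF3.

    1-based inclusive GFF3 coordinates become 0-based half-open.  The TSS
    of a ``+`` transcript is its (converted) start; of a ``-`` transcript,
    its ``end - 1``.  Biotype comes from ``biotype``/``gene_biotype``
    attributes and is binned to protein_coding vs non_coding.  A transcript
    whose Parent is not a seen gene is an error.
    """
    genes: dict[str, dict] = {}
    transcripts: list[tuple[str, str, int, int, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            if ftype != "gene" and ftype not in _TRANSCRIPT_TYPES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: bad GFF3 coordinates {start1}-{end1}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _gff3_attrs(attr_s)
            if ftype == "gene":
                gene_id = attrs.get("ID") or attrs.get("gene_id")
                if gene_id is None:
                    raise ParseError(f"{path}:{lineno}: gene without ID attribute")
                biotype = attrs.get("biotype") or attrs.get("gene_biotype") or "protein_coding"
                genes[gene_id] = {
                    "body": GenomicInterval(chrom, start1 - 1, end1),
                    "strand": strand,
                    "biotype": "protein_coding" if biotype == "protein_coding" else "non_coding",
                    "tss": [],
                }
            else:
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: transcript without Parent attribute")
                transcripts.append((parent, chrom, start1 - 1, end1, strand, lineno))
    for parent, chrom, start0, end0, strand, lineno in transcripts:
        gene = genes.get(parent)
        if gene is None:
            raise ParseError(f"{path}:{lineno}: transcript Parent {parent!r} is not a gene")
        tss = start0 if strand == "+" else end0 - 1
        gene["tss"].append(tss)
    models = []
    for gene_id, g in genes.items():
        tss_list = tuple(sorted(set(g["tss"]))) or (
            (g["body"].start,) if g["strand"] == "+" else (g["body"].end - 1,)
        )
        models.append(
            GeneModel(
                gene_id=gene_id,
                biotype=g["biotype"],
                body=g["body"],
                strand=g["strand"],
                tss_list=tss_list,
            )
        )
    models.sort(key=lambda m: (m.body.chrom, m.body.start, m.gene_id))
    return models


def write_gff3_genes(path: str | os.PathLike, genes: Sequence[GeneModel]) -> None:
    """Write gene models as GFF3 gene + transcript features (inverse of reader)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda m: (m.body.chrom, m.body.start, m.gene_id)):
            b = g.body
            fh.write(
                "\t".join(
                    [
                        b.chrom, "recat", "gene", str(b.start + 1), str(b.end), ".",
                        g.strand, ".", f"ID={g.gene_id};biotype={g.biotype}",
                    ]
                )
                + "\n"
            )
            for i, tss in enumerate(g.tss_list, start=1):
                # transcript spans TSS..gene 3' end on its strand
                if g.strand == "+":
                    t_start, t_end = tss, b.end
                else:
                    t_start, t_end = b.start, tss + 1
                fh.write(
                    "\t".join(
                        [
                            b.chrom, "recat", "mRNA", str(t_start + 1), str(t_end), ".",
                            g.strand, ".", f"ID={g.gene_id}.t{i};Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_matrix(df)
    return df


def write_matrix(path: str | os.PathLike, df: pd.DataFrame, index_label: str = "feature") -> None:
    validate_matrix(df)
    df.to_csv(path, sep="\t", index_label=index_label)


def validate_matrix(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        raise ValueError("duplicate row identifiers in matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate column identifiers in matrix")
    values = df.to_numpy()
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("matrix contains negative values")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a whole FASTA into memory as {name: uppercase sequence}."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def write_fasta(path: str | os.PathLike, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Minimal MEME motif format
# ---------------------------------------------------------------------------


def read_meme_pwm(path: str | os.PathLike):
    """Read the first motif of a minimal MEME file as a Pwm."""
    from Bio import motifs

    from .motif import Pwm

    with open(path) as fh:
        records = motifs.parse(fh, "minimal")
    if not records:
        raise ParseError(f"{path}: no motifs found")
    m = records[0]
    probs = np.column_stack([np.asarray(m.pwm[b], dtype=float) for b in "ACGT"])
    return Pwm(probs=probs, name=m.name or "motif")


def write_meme_pwm(path: str | os.PathLike, pwm) -> None:
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
        f"MOTIF {pwm.name}",
        # large nsites keeps Bio.motifs' internal count quantization lossless
        f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 1000000 E= 0",
    ]
    for row in pwm.probs:
        lines.append(" ".join(f"{p:.6f}" for p in row))
    lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Dense segmentations (BED4: chrom start end state)
# ---------------------------------------------------------------------------


def read_segmentation(path: str | os.PathLike, tissue: str) -> list[SegmentationRecord]:
    records = []
    for lineno, rec in enumerate(read_bed(path), start=1):
        if rec.name is None:
            raise ParseError(f"{path}: segment {lineno} lacks a state column")
        try:
            state = int(rec.name)
        except ValueError as exc:
            raise ParseError(f"{path}: segment {lineno}: bad state {rec.name!r}") from exc
        records.append(SegmentationRecord(rec.interval, state, tissue))
    records.sort(key=lambda r: r.interval)
    prev: SegmentationRecord | None = None
    for r in records:
        if (
            prev is not None
            and r.interval.chrom == prev.interval.chrom
            and r.interval.start < prev.interval.end
        ):
            raise ParseError(f"{path}: overlapping segments at {r.interval}")
        prev = r
    return records


def write_segmentation(path: str | os.PathLike, records: Iterable[SegmentationRecord]) -> None:
    write_bed(
        path,
        (BedRecord(r.interval, name=str(r.state)) for r in sorted(records, key=lambda r: r.interval)),
    )


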