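"""Seeded synthetic-data generator for every input the pipeline consumes.

The generator plants a known regulatory architecture -- REs with per-tissue
activity, TADs delimited by convergently oriented CTCF motifs, monotone
RE-signal/gene-expression links inside TADs, cross-species conservation,
and SNP-in-RE enrichment at a chosen odds ratio -- and emits the file
formats the analysis stages read, together with the ground truth needed to
score recovery.

Default scale is 2 chromosomes x 10 Mb with 300 genes, 600 REs and 40
TADs, which keeps the full pipeline comfortably inside a few minutes on a
single CPU.  All randomness flows from ``SimConfig.seed`` through
per-component child generators, so outputs are byte-identical across runs
and platforms regardless of which components are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import classify_re, RegulatoryElement
from .conservation import AlignmentBlock, AlignmentBlockMap
from .intervals import GeneModel, GenomicInterval, SegmentationRecord
from .motif import Pwm, reverse_complement, scan_sequence

__all__ = ["SimConfig", "GroundTruth", "Simulation", "TISSUES", "small_config"]

TISSUES = (
    "liver",
    "lung",
    "spleen",
    "muscle",
    "adipose",
    "cerebellum",
    "cortex",
    "hypothalamus",
)

ACTIVE_STATE_CHOICES = (1, 2, 3, 4, 5, 6, 8, 9, 11)
BACKGROUND_STATES = (14, 12, 13)  # low signal dominates, repressed interleaved
GRID = 200  # bp segmentation resolution; REs are planted on this grid

# CTCF-like 19-bp consensus (not palindromic, so orientation is decidable)
CTCF_CONSENSUS = "TGGCCACCAGGGGGCGCTA"

_RNG_STREAM = {"layout": 1, "seg": 2, "expr": 3, "ctcf": 4, "aln": 5, "snp": 6}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 10_000_000
    n_genes: int = 300
    n_tissues: int = 8
    n_reps: int = 2
    n_res: int = 600
    n_tads: int = 40
    n_true_links: int = 60
    link_rho: float = 0.9
    nb_dispersion: float = 0.05
    latent_sd: float = 1.2
    depth_range: tuple[float, float] = (0.5, 1.75)
    n_ctcf_decoys: int = 60
    tad_max_span: int = 1_000_000
    frac_conserved_re: float = 0.5
    frac_unmappable_re: float = 0.2
    snp_re_odds: float = 2.5
    snp_categories: tuple[str, ...] = ("geQTL", "mQTL", "sQTL")
    n_snps_per_category: int = 5_000
    baseline_in_re_frac: float = 0.05
    n_marker_genes: int = 20

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_len", "n_genes", "n_tissues", "n_reps",
                     "n_res", "n_tads", "n_true_links"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        # 0 is allowed as the exact-null boundary used for calibration runs
        if not 0.0 <= self.link_rho <= 1.0:
            raise ValueError("link_rho must lie in [0, 1]")

    @property
    def tissues(self) -> tuple[str, ...]:
        if self.n_tissues <= len(TISSUES):
            return TISSUES[: self.n_tissues]
        extra = tuple(f"tissue{i}" for i in range(len(TISSUES) + 1, self.n_tissues + 1))
        return TISSUES + extra

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(
            f"{t}_r{j}" for t in self.tissues for j in range(1, self.n_reps + 1)
        )

    @property
    def tissue_map(self) -> dict[str, str]:
        return {s: s.rsplit("_r", 1)[0] for s in self.samples}

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(f"chr{i}" for i in range(1, self.n_chroms + 1))

    @property
    def genome_size(self) -> int:
        return self.n_chroms * self.chrom_len


@dataclass
class GroundTruth:
    re_ids: list[str]
    res: list[RegulatoryElement]  # classified, with planted tissue sets
    genes: list[GeneModel]
    extra_tss: list[tuple[str, int]]
    tads: list[GenomicInterval]
    anchors: list[tuple[str, int, int]]  # chrom, fwd motif start, rev motif start
    links: set[tuple[str, str]]
    marker_genes: list[str]

    def __post_init__(self) -> None:
        tad_index = {i: t for i, t in enumerate(self.tads)}
        re_by_id = dict(zip(self.re_ids, self.res))
        gene_by_id = {g.gene_id: g for g in self.genes}
        for rid, gid in self.links:
            re = re_by_id[rid]
            gene = gene_by_id[gid]
            ok = any(
                t.chrom == re.interval.chrom
                and t.contains(re.interval.midpoint)
                and t.contains(gene.tss_5prime)
                for t in tad_index.values()
            )
            if not ok:
                raise ValueError(f"link {rid}->{gid} does not share a TAD")


class Simulation:
    """Deterministic scenario built from a :class:`SimConfig`.

    The layout (TADs, genes, REs, links) is constructed eagerly; the data
    products (segmentations, count matrices, genome/peaks, alignment map,
    SNPs) are generated on demand from independent child RNG streams.
    """

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.truth = _build_layout(cfg, self._rng("layout"))

    def _rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.cfg.seed), _RNG_STREAM[stream]])

    # -- chromatin-state segmentations ------------------------------------

    def segmentations(self) -> dict[str, list[SegmentationRecord]]:
        """Per-tissue dense segmentations tiling each chromosome.

        Every planted RE active in a tissue is written as 1-3 abutting
        segments with states from the active set; everything else is
        background (state 14 interleaved with repressed 12/13).
        """
        cfg = self.cfg
        rng = self._rng("seg")
        out: dict[str, list[SegmentationRecord]] = {}
        res_by_chrom: dict[str, list[tuple[GenomicInterval, frozenset]]] = {
            c: [] for c in cfg.chroms
        }
        for re in self.truth.res:
            res_by_chrom[re.interval.chrom].append((re.interval, re.active_tissues))
        for c in cfg.chroms:
            res_by_chrom[c].sort(key=lambda x: x[0].start)
        for tissue in cfg.tissues:
            records: list[SegmentationRecord] = []
            for chrom in cfg.chroms:
                pos = 0
                for iv, tissues in res_by_chrom[chrom]:
                    if pos < iv.start:
                        records.extend(_background(chrom, pos, iv.start, tissue, rng))
                    if tissue in tissues:
                        records.extend(_active_run(chrom, iv, tissue, rng))
                    else:
                        records.extend(_background(chrom, iv.start, iv.end, tissue, rng))
                    pos = iv.end
                if pos < cfg.chrom_len:
                    records.extend(_background(chrom, pos, cfg.chrom_len, tissue, rng))
            out[tissue] = records
        return out

    # -- expression and H3K27ac signal ------------------------------------

    def expression_and_signal(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Gene-count and RE H3K27ac-count matrices over tissue x replicate.

        Each planted link shares a per-tissue latent activity that drives
        both negative-binomial means through the same monotone response, so
        the expected Spearman correlation of a true pair across samples is
        about ``link_rho``; unlinked features vary independently.  Library
        depths span >= 3-fold to exercise TMM.
        """
        cfg = self.cfg
        rng = self._rng("expr")
        truth = self.truth
        samples = cfg.samples
        n_s = len(samples)
        tissue_of = np.array(
            [cfg.tissues.index(cfg.tissue_map[s]) for s in samples]
        )
        depths = np.geomspace(cfg.depth_range[0], cfg.depth_range[1], n_s)
        depths = depths[rng.permutation(n_s)]

        # latent normal correlation reproducing the target Spearman for a
        # bivariate normal:  r = 2 sin(pi * rho_s / 6)
        r = min(1.0, 2.0 * np.sin(np.pi * cfg.link_rho / 6.0))

        gene_ids = [g.gene_id for g in truth.genes]
        re_ids = truth.re_ids
        gene_latent = rng.standard_normal((len(gene_ids), n_s))
        re_latent = rng.standard_normal((len(re_ids), n_s))

        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        re_pos = {rid: i for i, rid in enumerate(re_ids)}
        # baseline abundances drawn up front so the latent coupling can be
        # corrected for counting-noise attenuation per linked pair
        gene_base = np.maximum(np.exp(rng.normal(np.log(300.0), 0.7, len(gene_ids))), 120.0)
        re_base = np.maximum(np.exp(rng.normal(np.log(200.0), 0.7, len(re_ids))), 100.0)

        def _attenuation(base: float) -> float:
            # log-scale noise variance of an NB count at the baseline mean,
            # relative to the latent signal variance
            cv2 = cfg.nb_dispersion + 1.0 / base
            noise_var = np.log1p(cv2)
            return cfg.latent_sd / np.sqrt(cfg.latent_sd**2 + noise_var)

        # the shared activity is a per-sample quantity with tissue structure:
        # the same sample's regulatory activity drives both its RE signal
        # and its target's expression, so replicates stay informative
        tissue_frac = 0.6
        for rid, gid in sorted(truth.links):
            gi, ri_ = gene_pos[gid], re_pos[rid]
            # compensate NB attenuation so the observable count-scale
            # correlation realizes ~link_rho rather than an eroded value
            r_eff = min(1.0, r / (_attenuation(gene_base[gi]) * _attenuation(re_base[ri_])))
            b_t = rng.standard_normal(cfg.n_tissues)
            eta = rng.standard_normal(n_s)
            shared = np.sqrt(tissue_frac) * b_t[tissue_of] + np.sqrt(1 - tissue_frac) * eta
            e1 = rng.standard_normal(n_s)
            e2 = rng.standard_normal(n_s)
            a = np.sqrt(r_eff)
            b = np.sqrt(max(0.0, 1.0 - r_eff))
            gene_latent[gi] = a * shared + b * e1
            re_latent[ri_] = a * shared + b * e2

        gene_mean = gene_base[:, None] * np.exp(cfg.latent_sd * gene_latent) * depths
        re_mean = re_base[:, None] * np.exp(cfg.latent_sd * re_latent) * depths

        # marker genes: strong single-tissue elevation for the
        # expressed/tissue-specific flag logic
        for i, gid in enumerate(truth.marker_genes):
            gi = gene_pos[gid]
            boost = np.where(tissue_of == (i % cfg.n_tissues), 12.0, 0.8)
            gene_mean[gi] = gene_base[gi] * boost * depths

        gene_counts = _nb_sample(rng, gene_mean, cfg.nb_dispersion)
        re_counts = _nb_sample(rng, re_mean, cfg.nb_dispersion)
        genes_df = pd.DataFrame(gene_counts, index=gene_ids, columns=list(samples))
        res_df = pd.DataFrame(re_counts, index=re_ids, columns=list(samples))
        return genes_df, res_df

    # -- CTCF architecture --------------------------------------------------

    def ctcf_architecture(self) -> tuple[dict[str, str], list[GenomicInterval], Pwm]:
        """Genome FASTA dict, pooled CTCF peaks and the motif PWM.

        Each planted TAD boundary pair is an exact consensus embedding
        (forward at the left anchor, reverse complement at the right).
        Decoy peaks contain no motif above the scanning threshold; they are
        resampled until clean so TAD prediction recovers the planted
        domains exactly.
        """
        cfg = self.cfg
        rng = self._rng("ctcf")
        pwm = _ctcf_pwm()
        buffers = {
            c: bytearray(_random_bases(rng, cfg.chrom_len), "ascii") for c in cfg.chroms
        }
        w = pwm.length
        rc = reverse_complement(CTCF_CONSENSUS).encode("ascii")
        fwd_bytes = CTCF_CONSENSUS.encode("ascii")
        peaks: list[GenomicInterval] = []
        for chrom, fwd, rev in self.truth.anchors:
            buffers[chrom][fwd : fwd + w] = fwd_bytes
            buffers[chrom][rev : rev + w] = rc
            for anchor in (fwd, rev):
                mid = anchor + w // 2
                peaks.append(GenomicInterval(chrom, mid - 100, mid + 100))

        # decoy peaks: motif-free 200-bp windows
        anchor_spans = sorted(peaks)
        n_placed = 0
        attempts = 0
        decoys: list[GenomicInterval] = []
        while n_placed < cfg.n_ctcf_decoys and attempts < cfg.n_ctcf_decoys * 50:
            attempts += 1
            chrom = cfg.chroms[int(rng.integers(cfg.n_chroms))]
            start = int(rng.integers(1_000, cfg.chrom_len - 1_200))
            cand = GenomicInterval(chrom, start, start + 200)
            if any(cand.overlaps(p) for p in anchor_spans + decoys):
                continue
            _scrub_motif(buffers[chrom], cand, pwm, rng)
            decoys.append(cand)
            n_placed += 1
        peaks.extend(decoys)
        peaks.sort()
        genome = {c: buf.decode("ascii") for c, buf in buffers.items()}
        return genome, peaks, pwm

    # -- alignment map ------------------------------------------------------

    def alignment_map(
        self,
    ) -> tuple[AlignmentBlockMap, list[GenomicInterval], pd.DataFrame]:
        """Pairwise block map, target-species RE catalog, and per-RE truth.

        Designated unmappable REs fall wholly inside alignment gaps;
        every other RE is fully covered by blocks, and the conserved subset
        receives a target-species RE exactly at its image.
        """
        cfg = self.cfg
        rng = self._rng("aln")
        truth = self.truth
        status: dict[str, str] = {}
        for rid in truth.re_ids:
            u = rng.random()
            if u < cfg.frac_unmappable_re:
                status[rid] = "unmapped"
            elif rng.random() < cfg.frac_conserved_re:
                status[rid] = "conserved"
            else:
                status[rid] = "mapped"

        re_by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {
            c: [] for c in cfg.chroms
        }
        for rid, re in zip(truth.re_ids, truth.res):
            re_by_chrom[re.interval.chrom].append((rid, re.interval))

        blocks: list[AlignmentBlock] = []
        target_res: list[GenomicInterval] = []
        rows = []
        for chrom in cfg.chroms:
            items = sorted(re_by_chrom[chrom], key=lambda x: x[1].start)
            gaps = [
                GenomicInterval(chrom, max(0, iv.start - 100), min(cfg.chrom_len, iv.end + 100))
                for rid, iv in items
                if status[rid] == "unmapped"
            ]
            runs = _complement(chrom, gaps, cfg.chrom_len)
            tgt_chrom = "t" + chrom
            cursor = 10_000
            chrom_blocks: list[AlignmentBlock] = []
            for run in runs:
                pos = run.start
                while pos < run.end:
                    size = min(int(rng.integers(20_000, 80_000)), run.end - pos)
                    src = GenomicInterval(chrom, pos, pos + size)
                    tgt = GenomicInterval(tgt_chrom, cursor, cursor + size)
                    chrom_blocks.append(AlignmentBlock(src, tgt, "+"))
                    cursor += size + int(rng.integers(0, 5_000))
                    pos += size
            blocks.extend(chrom_blocks)
            for rid, iv in items:
                if status[rid] == "unmapped":
                    rows.append((rid, False, False))
                    continue
                image = _image_span(iv, chrom_blocks)
                if status[rid] == "conserved":
                    target_res.append(image)
                rows.append((rid, True, status[rid] == "conserved"))
        target_res.sort()
        truth_df = pd.DataFrame(rows, columns=["re_id", "mapped", "conserved"])
        truth_df = truth_df.sort_values("re_id").reset_index(drop=True)
        return AlignmentBlockMap(blocks, "source", "target"), target_res, truth_df

    # -- SNPs ----------------------------------------------------------------

    def snps(self) -> pd.DataFrame:
        """SNP table with p-values, category labels and in-RE ground truth.

        Categorized SNPs land inside REs with odds ``snp_re_odds`` relative
        to uncategorized SNPs; in-RE SNPs draw p-values skewed to small
        values (Beta(0.4, 1)), out-of-RE SNPs from Uniform(0, 1).
        """
        cfg = self.cfg
        rng = self._rng("snp")
        re_ivs = [re.interval for re in self.truth.res]
        lengths = np.array([iv.length for iv in re_ivs], dtype=float)
        weights = lengths / lengths.sum()
        from .intervals import IntervalIndex

        catalog = IntervalIndex(re_ivs)

        q0 = cfg.baseline_in_re_frac / (1.0 - cfg.baseline_in_re_frac)
        odds_cat = cfg.snp_re_odds * q0
        p_cat = odds_cat / (1.0 + odds_cat)

        groups = [("", cfg.baseline_in_re_frac)] + [
            (cat, p_cat) for cat in cfg.snp_categories
        ]
        frames = []
        for cat, p_in in groups:
            n = cfg.n_snps_per_category
            in_re = rng.random(n) < p_in
            chroms = np.empty(n, dtype=object)
            pos = np.empty(n, dtype=np.int64)
            n_in = int(in_re.sum())
            if n_in:
                idx = rng.choice(len(re_ivs), size=n_in, p=weights)
                offs = rng.random(n_in)
                chosen = [re_ivs[i] for i in idx]
                chroms[in_re] = [iv.chrom for iv in chosen]
                pos[in_re] = [
                    iv.start + int(o * iv.length) for iv, o in zip(chosen, offs)
                ]
            n_out = n - n_in
            if n_out:
                oc, op = _sample_outside(rng, cfg, catalog, n_out)
                chroms[~in_re] = oc
                pos[~in_re] = op
            pv = np.where(
                in_re,
                rng.beta(0.4, 1.0, n),
                rng.uniform(0.0, 1.0, n),
            )
            pv = np.clip(pv, 1e-12, 1.0)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chroms,
                        "pos": pos,
                        "pvalue": pv,
                        "categories": cat,
                        "true_in_re": in_re,
                    }
                )
            )
        snps = pd.concat(frames, ignore_index=True)
        # a few SNPs belong to multiple categories
        cat_rows = np.nonzero((snps["categories"] != "").to_numpy())[0]
        if len(cfg.snp_categories) > 1 and len(cat_rows):
            extra = cat_rows[rng.random(len(cat_rows)) < 0.05]
            cats = list(cfg.snp_categories)
            for i in extra:
                current = snps.at[i, "categories"]
                others = [c for c in cats if c != current]
                snps.at[i, "categories"] = (
                    current + ";" + others[int(rng.integers(len(others)))]
                )
        return snps

    # -- writing --------------------------------------------------------------

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        """Write every simulated input plus ground-truth files to a directory."""
        from . import io as rio
        from .annotate import catalog_to_bed_records
        from .conservation import write_block_map

        out = Path(outdir)
        (out / "segmentations").mkdir(parents=True, exist_ok=True)
        (out / "ground_truth").mkdir(exist_ok=True)
        paths: dict[str, Path] = {}

        for tissue, records in self.segmentations().items():
            p = out / "segmentations" / f"{tissue}.bed"
            rio.write_segmentation(p, records)
            paths[f"segmentation_{tissue}"] = p

        rio.write_gff3_genes(out / "genes.gff3", self.truth.genes)
        paths["genes"] = out / "genes.gff3"

        genes_df, res_df = self.expression_and_signal()
        rio.write_matrix(out / "gene_counts.tsv", genes_df, index_label="gene_id")
        rio.write_matrix(out / "re_counts.tsv", res_df, index_label="re_id")
        paths["gene_counts"] = out / "gene_counts.tsv"
        paths["re_counts"] = out / "re_counts.tsv"

        genome, peaks, pwm = self.ctcf_architecture()
        rio.write_fasta(out / "genome.fa", genome)
        rio.write_bed(out / "ctcf_peaks.bed", [rio.BedRecord(p) for p in peaks])
        rio.write_meme_pwm(out / "ctcf_motif.meme", pwm)
        paths["genome"] = out / "genome.fa"
        paths["ctcf_peaks"] = out / "ctcf_peaks.bed"
        paths["ctcf_motif"] = out / "ctcf_motif.meme"

        block_map, target_res, cons_truth = self.alignment_map()
        write_block_map(out / "alignment_blocks.tsv", block_map)
        rio.write_bed(out / "target_catalog.bed", [rio.BedRecord(iv) for iv in target_res])
        cons_truth.to_csv(out / "ground_truth" / "conservation.tsv", sep="\t", index=False)
        paths["alignment"] = out / "alignment_blocks.tsv"
        paths["target_catalog"] = out / "target_catalog.bed"

        snps = self.snps()
        snps.to_csv(out / "snps.tsv", sep="\t", index=False)
        paths["snps"] = out / "snps.tsv"

        rio.write_bed(out / "ground_truth" / "true_res.bed",
                      catalog_to_bed_records(self.truth.res))
        rio.write_bed(
            out / "ground_truth" / "true_tads.bed",
            [rio.BedRecord(t) for t in self.truth.tads],
        )
        pd.DataFrame(sorted(self.truth.links), columns=["re_id", "gene_id"]).to_csv(
            out / "ground_truth" / "true_links.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"sample": list(self.cfg.samples),
             "tissue": [self.cfg.tissue_map[s] for s in self.cfg.samples]}
        ).to_csv(out / "samples.tsv", sep="\t", index=False)
        pd.DataFrame(self.truth.extra_tss, columns=["chrom", "pos"]).to_csv(
            out / "ground_truth" / "extra_tss.tsv", sep="\t", index=False
        )
        return paths


# ---------------------------------------------------------------------------
# layout construction
# ---------------------------------------------------------------------------


def _build_layout(cfg: SimConfig, rng: np.random.Generator) -> GroundTruth:
    tads: list[GenomicInterval] = []
    anchors: list[tuple[str, int, int]] = []
    w = len(CTCF_CONSENSUS)
    per_chrom = [cfg.n_tads // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_tads % cfg.n_chroms):
        per_chrom[i] += 1
    for chrom, n_t in zip(cfg.chroms, per_chrom):
        if n_t == 0:
            continue
        budget = (cfg.chrom_len - 100_000) / n_t
        if budget < 20_000:
            raise ValueError("TAD density exceeds chromosome capacity")
        cursor = 50_000
        for _ in range(n_t):
            span = int(budget * rng.uniform(0.55, 0.75))
            span = min(span, int(0.9 * cfg.tad_max_span))
            gap = int(budget * rng.uniform(0.15, 0.30))
            fwd = cursor
            rev = cursor + span - w
            tads.append(GenomicInterval(chrom, fwd + w // 2, rev + w // 2))
            anchors.append((chrom, fwd, rev))
            cursor += span + gap
            if cursor > cfg.chrom_len - 50_000:
                raise ValueError("TAD placement exceeded chromosome capacity")

    genes, _occupied = _place_genes(cfg, rng, tads)
    extra_tss = _place_extra_tss(cfg, rng, genes)
    re_items = _place_res(cfg, rng, tads, genes, extra_tss)

    # identifiers follow sorted interval order so the pipeline's catalog
    # (which recovers exactly the planted intervals) assigns matching names
    re_items.sort(key=lambda x: x[0])
    re_ids = [f"RE{i:06d}" for i in range(len(re_items))]
    res = [
        RegulatoryElement(iv, tissues, classify_re(iv, genes, extra_tss))
        for iv, tissues in re_items
    ]

    links = _choose_links(cfg, rng, re_ids, res, genes, tads)
    marker_pool = [
        g.gene_id
        for g in genes
        if g.biotype == "protein_coding"
        and not _in_any_tad(g.tss_5prime, g.body.chrom, tads)
        and g.gene_id not in {gid for _, gid in links}
    ]
    marker_genes = marker_pool[: cfg.n_marker_genes]
    return GroundTruth(
        re_ids=re_ids,
        res=res,
        genes=genes,
        extra_tss=extra_tss,
        tads=tads,
        anchors=anchors,
        links=links,
        marker_genes=marker_genes,
    )


def _in_any_tad(pos: int, chrom: str, tads: Sequence[GenomicInterval]) -> bool:
    return any(t.chrom == chrom and t.contains(pos) for t in tads)


def _overlaps_any(start: int, end: int, occupied: list[tuple[int, int]], margin: int = 0) -> bool:
    return any(start - margin < e and end + margin > s for s, e in occupied)


def _place_genes(
    cfg: SimConfig, rng: np.random.Generator, tads: Sequence[GenomicInterval]
) -> tuple[list[GeneModel], dict[str, list[tuple[int, int]]]]:
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chroms}
    genes: list[GeneModel] = []
    tad_list = list(tads)
    n_inside = int(round(cfg.n_genes * 0.85))
    for gi in range(cfg.n_genes):
        length = int(rng.integers(2_000, 9_000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "protein_coding" if rng.random() < 0.9 else "non_coding"
        placed = False
        for _ in range(200):
            if gi < n_inside and tad_list:
                tad = tad_list[int(rng.integers(len(tad_list)))]
                chrom = tad.chrom
                lo, hi = tad.start + 2_500, tad.end - length - 2_500
            else:
                chrom = cfg.chroms[int(rng.integers(cfg.n_chroms))]
                lo, hi = 10_000, cfg.chrom_len - length - 10_000
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length
            if _overlaps_any(start, end, occupied[chrom], margin=500):
                continue
            occupied[chrom].append((start, end))
            body = GenomicInterval(chrom, start, end)
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(f"G{gi:05d}", biotype, body, strand, (tss,))
            )
            placed = True
            break
        if not placed:
            raise ValueError("gene density exceeds chromosome capacity")
    genes.sort(key=lambda g: (g.body.chrom, g.body.start))
    return genes, occupied


def _place_extra_tss(
    cfg: SimConfig, rng: np.random.Generator, genes: Sequence[GeneModel]
) -> list[tuple[str, int]]:
    """Unannotated TSS positions, placed clear of annotated genes."""
    out: list[tuple[str, int]] = []
    gene_spans = {c: [] for c in cfg.chroms}
    for g in genes:
        gene_spans[g.body.chrom].append((g.body.start, g.body.end))
    n = max(5, cfg.n_genes // 15)
    tries = 0
    while len(out) < n and tries < n * 100:
        tries += 1
        chrom = cfg.chroms[int(rng.integers(cfg.n_chroms))]
        pos = int(rng.integers(10_000, cfg.chrom_len - 10_000))
        if _overlaps_any(pos, pos + 1, gene_spans[chrom], margin=4_500):
            continue
        out.append((chrom, pos))
    out.sort()
    return out


def _snap(x: int) -> int:
    return (x // GRID) * GRID


def _place_res(
    cfg: SimConfig,
    rng: np.random.Generator,
    tads: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    extra_tss: Sequence[tuple[str, int]],
) -> list[tuple[GenomicInterval, frozenset]]:
    """Plant grid-aligned REs with promoter / genic / intergenic / excluded
    placement intents.  The recorded ground-truth class always comes from
    the classification rule applied to the final coordinates, so a failed
    intent only shifts the class mix, never corrupts the truth."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chroms}
    coding_tss: dict[str, list[int]] = {c: [] for c in cfg.chroms}
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chroms}
    genic_candidates: list[GeneModel] = []
    for g in genes:
        gene_spans[g.body.chrom].append((g.body.start, g.body.end))
        if g.biotype == "protein_coding":
            coding_tss[g.body.chrom].extend(g.tss_list)
            if g.body.length >= 4_600:
                genic_candidates.append(g)

    tad_list = list(tads)
    items: list[tuple[GenomicInterval, frozenset]] = []
    intents = rng.choice(
        ["promoter", "genic", "intergenic", "excluded"],
        size=cfg.n_res,
        p=[0.25, 0.30, 0.40, 0.05],
    )
    n_inside = int(round(cfg.n_res * 0.8))
    for ri in range(cfg.n_res):
        length = GRID * int(rng.integers(2, 8))  # 400..1400 bp
        placed = None
        # a hard-to-satisfy intent falls back to free placement; the truth
        # class always comes from the final coordinates, so this only
        # shifts the class mix
        for intent in (intents[ri], "free"):
            for _ in range(300):
                if intent == "free":
                    chrom = cfg.chroms[int(rng.integers(cfg.n_chroms))]
                    cand = (chrom, int(rng.integers(10_000, cfg.chrom_len - length - 10_000)))
                else:
                    cand = _propose_re(
                        cfg, rng, intent, length, tad_list if ri < n_inside else [],
                        genes, genic_candidates, extra_tss,
                    )
                if cand is None:
                    continue
                chrom, start = cand
                start = _snap(start)
                end = start + length
                if start < 2_000 or end > cfg.chrom_len - 2_000:
                    continue
                if _overlaps_any(start, end, occupied[chrom], margin=600):
                    continue
                occupied[chrom].append((start, end))
                placed = GenomicInterval(chrom, start, end)
                break
            if placed is not None:
                break
        if placed is None:
            raise ValueError("RE density exceeds chromosome capacity")
        items.append((placed, _activity_set(cfg, rng)))
    return items


def _propose_re(
    cfg: SimConfig,
    rng: np.random.Generator,
    intent: str,
    length: int,
    tad_list: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    genic_candidates: Sequence[GeneModel],
    extra_tss: Sequence[tuple[str, int]],
) -> tuple[str, int] | None:
    def in_tad_bounds(chrom: str, start: int) -> bool:
        if not tad_list:
            return True
        mid = start + length // 2
        return _in_any_tad(mid, chrom, tad_list)

    if intent == "promoter":
        coding = [g for g in genes if g.biotype == "protein_coding"]
        g = coding[int(rng.integers(len(coding)))]
        tss = g.tss_list[0]
        start = tss + int(rng.integers(-1_500, 1_200))
        if tad_list and not in_tad_bounds(g.body.chrom, start):
            return None
        return (g.body.chrom, max(0, start))
    if intent == "genic":
        if not genic_candidates:
            return None
        g = genic_candidates[int(rng.integers(len(genic_candidates)))]
        body, tss = g.body, g.tss_list[0]
        if g.strand == "+":
            lo, hi = tss + 2_600, body.end - length - 100
        else:
            lo, hi = body.start + 100, tss - 2_600 - length
        if hi <= lo:
            return None
        start = int(rng.integers(lo, hi))
        if tad_list and not in_tad_bounds(body.chrom, start):
            return None
        return (body.chrom, start)
    if intent == "excluded":
        if not extra_tss:
            return None
        chrom, pos = extra_tss[int(rng.integers(len(extra_tss)))]
        return (chrom, pos + int(rng.integers(-1_500, 1_200)))
    # intergenic
    if tad_list:
        tad = tad_list[int(rng.integers(len(tad_list)))]
        chrom = tad.chrom
        lo, hi = tad.start + 500, tad.end - length - 500
    else:
        chrom = cfg.chroms[int(rng.integers(cfg.n_chroms))]
        lo, hi = 10_000, cfg.chrom_len - length - 10_000
    if hi <= lo:
        return None
    start = int(rng.integers(lo, hi))
    # verify intergenic intent quickly: clear of gene bodies and coding TSSs
    for g in genes:
        if g.body.chrom != chrom:
            continue
        if start < g.body.end and start + length > g.body.start:
            return None
        for tss in g.tss_list:
            if abs(tss - start) < 2_700 or abs(tss - (start + length)) < 2_700:
                return None
    return (chrom, start)


def _activity_set(cfg: SimConfig, rng: np.random.Generator) -> frozenset:
    tissues = cfg.tissues
    if rng.random() < 0.3 or len(tissues) == 1:
        return frozenset([tissues[int(rng.integers(len(tissues)))]])
    k = 2 + int(rng.binomial(max(0, len(tissues) - 2), 0.4))
    chosen = rng.choice(len(tissues), size=min(k, len(tissues)), replace=False)
    return frozenset(tissues[i] for i in chosen)


def _choose_links(
    cfg: SimConfig,
    rng: np.random.Generator,
    re_ids: Sequence[str],
    res: Sequence[RegulatoryElement],
    genes: Sequence[GeneModel],
    tads: Sequence[GenomicInterval],
) -> set[tuple[str, str]]:
    """Distinct-RE, distinct-gene pairs sharing a TAD."""
    tad_res: dict[int, list[str]] = {i: [] for i in range(len(tads))}
    tad_genes: dict[int, list[str]] = {i: [] for i in range(len(tads))}
    for rid, re in zip(re_ids, res):
        for i, t in enumerate(tads):
            if t.chrom == re.interval.chrom and t.contains(re.interval.midpoint):
                tad_res[i].append(rid)
                break
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        for i, t in enumerate(tads):
            if t.chrom == g.body.chrom and t.contains(g.tss_5prime):
                tad_genes[i].append(g.gene_id)
                break
    links: set[tuple[str, str]] = set()
    used_res: set[str] = set()
    used_genes: set[str] = set()
    candidates = [i for i in range(len(tads)) if tad_res[i] and tad_genes[i]]
    tries = 0
    while len(links) < cfg.n_true_links and tries < cfg.n_true_links * 200:
        tries += 1
        if not candidates:
            break
        i = candidates[int(rng.integers(len(candidates)))]
        rid_pool = [r for r in tad_res[i] if r not in used_res]
        gid_pool = [g for g in tad_genes[i] if g not in used_genes]
        if not rid_pool or not gid_pool:
            continue
        rid = rid_pool[int(rng.integers(len(rid_pool)))]
        gid = gid_pool[int(rng.integers(len(gid_pool)))]
        links.add((rid, gid))
        used_res.add(rid)
        used_genes.add(gid)
    if len(links) < cfg.n_true_links:
        raise ValueError("could not place the requested number of true links")
    return links


# ---------------------------------------------------------------------------
# segmentation helpers
# ---------------------------------------------------------------------------


def _background(
    chrom: str, start: int, end: int, tissue: str, rng: np.random.Generator
) -> list[SegmentationRecord]:
    records = []
    pos = start
    while pos < end:
        size = min(GRID * int(rng.integers(5, 60)), end - pos)
        state = 14 if rng.random() < 0.8 else int(rng.choice((12, 13)))
        records.append(
            SegmentationRecord(GenomicInterval(chrom, pos, pos + size), state, tissue)
        )
        pos += size
    return records


def _active_run(
    chrom: str, iv: GenomicInterval, tissue: str, rng: np.random.Generator
) -> list[SegmentationRecord]:
    n_seg = int(rng.integers(1, 4))
    cuts = sorted(
        {iv.start, iv.end}
        | {
            _snap(int(rng.integers(iv.start + 1, iv.end)))
            for _ in range(n_seg - 1)
        }
    )
    cuts = [c for c in cuts if iv.start <= c <= iv.end]
    records = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b <= a:
            continue
        state = int(rng.choice(ACTIVE_STATE_CHOICES))
        records.append(SegmentationRecord(GenomicInterval(chrom, a, b), state, tissue))
    return records


# ---------------------------------------------------------------------------
# counts, sequence, alignment helpers
# ---------------------------------------------------------------------------


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2.

    ``dispersion == 0`` is the deterministic limit: counts are the rounded
    means (used by the noiseless construction tests).
    """
    mean = np.maximum(mean, 1e-8)
    if dispersion <= 0:
        return np.rint(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    codes = rng.integers(0, 4, size=n, dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _scrub_motif(
    buf: bytearray, region: GenomicInterval, pwm: Pwm, rng: np.random.Generator
) -> None:
    """Resample a window in place until it holds no motif hit at the default
    scanning threshold.  A margin of one motif width on each side keeps hits
    from straddling the window edges."""
    w = pwm.length
    lo = max(0, region.start - w)
    hi = min(len(buf), region.end + w)
    r_lo, r_hi = region.start - lo, region.end - lo
    for _ in range(50):
        sub = buf[lo:hi].decode("ascii")
        hits = scan_sequence(sub, pwm, 1e-4, chrom="x")
        # only hits sharing bases with the window can orient the decoy peak;
        # hits wholly inside the flanks are outside the peak span
        if not any(h.interval.start < r_hi and h.interval.end > r_lo for h in hits):
            return
        buf[region.start : region.end] = _random_bases(rng, region.length).encode("ascii")
    raise RuntimeError("failed to scrub decoy peak of motif hits")


def _complement(
    chrom: str, gaps: Sequence[GenomicInterval], chrom_len: int
) -> list[GenomicInterval]:
    from .intervals import merge_intervals

    out = []
    pos = 0
    for g in merge_intervals(gaps, bookended=True):
        if g.start > pos:
            out.append(GenomicInterval(chrom, pos, g.start))
        pos = max(pos, g.end)
    if pos < chrom_len:
        out.append(GenomicInterval(chrom, pos, chrom_len))
    return out


def _image_span(
    iv: GenomicInterval, blocks: Sequence[AlignmentBlock]
) -> GenomicInterval:
    """Target span of a fully aligned source interval (construction-side
    arithmetic, independent of the mapping stage under test)."""

    def map_pos(p: int) -> int:
        for b in blocks:
            if b.src.start <= p < b.src.end:
                return b.tgt.start + (p - b.src.start)
        raise ValueError(f"position {p} not covered by any block")

    lo = map_pos(iv.start)
    hi = map_pos(iv.end - 1) + 1
    return GenomicInterval(blocks[0].tgt.chrom, lo, hi)


def _ctcf_pwm() -> Pwm:
    base_index = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(CTCF_CONSENSUS), 4), 0.04)
    for i, b in enumerate(CTCF_CONSENSUS):
        probs[i] = 0.04
        probs[i, base_index[b]] = 0.88
    return Pwm(probs, name="CTCF_synthetic")


def _sample_outside(
    rng: np.random.Generator, cfg: SimConfig, catalog, n: int
) -> tuple[list[str], np.ndarray]:
    chroms_out: list[str] = []
    pos_out: list[int] = []
    while len(pos_out) < n:
        batch = max(64, n - len(pos_out))
        ci = rng.integers(0, cfg.n_chroms, size=batch)
        ps = rng.integers(0, cfg.chrom_len, size=batch)
        for c, p in zip(ci, ps):
            chrom = cfg.chroms[int(c)]
            if catalog.contains_point(chrom, int(p)):
                continue
            chroms_out.append(chrom)
            pos_out.append(int(p))
            if len(pos_out) == n:
                break
    return chroms_out, np.array(pos_out, dtype=np.int64)


# convenience: a scaled-down config for quick tests
def small_config(seed: int = 0, **overrides) -> SimConfig:
    base = SimConfig(
        seed=seed,
        n_chroms=2,
        chrom_len=2_000_000,
        n_genes=80,
        n_res=120,
        n_tads=12,
        n_true_links=12,
        n_ctcf_decoys=15,
        n_snps_per_category=1_000,
    )
    return replace(base, **overrides)
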