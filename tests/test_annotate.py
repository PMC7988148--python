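"""RE catalog construction vs per-base brute-force oracles."""

import numpy as np
import pytest

from recat.annotate import (
    ACTIVE_STATES,
    RegulatoryElement,
    classify_re,
    combine_tissues,
    consolidate_active,
    open_chromatin_support,
    state_feature_enrichment,
)
from recat.intervals import GeneModel, GenomicInterval, SegmentationRecord

CHROM_LEN = 300_000


def random_tiling(rng, tissue, chrom="chr1", chrom_len=CHROM_LEN):
    """Random dense segmentation covering the chromosome without gaps."""
    records = []
    pos = 0
    while pos < chrom_len:
        size = int(rng.integers(200, 3_000))
        end = min(chrom_len, pos + size)
        state = int(rng.integers(1, 15))
        records.append(SegmentationRecord(GenomicInterval(chrom, pos, end), state, tissue))
        pos = end
    return records


def active_mask(records, chrom_len=CHROM_LEN):
    mask = np.zeros(chrom_len, dtype=bool)
    for r in records:
        if r.state in ACTIVE_STATES:
            mask[r.interval.start : r.interval.end] = True
    return mask


def mask_runs(mask, chrom="chr1"):
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    return [
        GenomicInterval(chrom, int(s), int(e))
        for s, e in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0])
    ]


class TestConsolidateActive:
    def test_adjacent_active_states_merge(self):
        recs = [
            SegmentationRecord(GenomicInterval("chr1", 100, 300), 2, "liver"),
            SegmentationRecord(GenomicInterval("chr1", 300, 500), 4, "liver"),
            SegmentationRecord(GenomicInterval("chr1", 500, 900), 14, "liver"),
        ]
        assert consolidate_active(recs) == [GenomicInterval("chr1", 100, 500)]

    def test_no_active_states(self):
        recs = [
            SegmentationRecord(GenomicInterval("chr1", 0, 100), 14, "liver"),
            SegmentationRecord(GenomicInterval("chr1", 100, 200), 12, "liver"),
        ]
        assert consolidate_active(recs) == []

    def test_overlapping_segments_rejected(self):
        recs = [
            SegmentationRecord(GenomicInterval("chr1", 0, 300), 14, "liver"),
            SegmentationRecord(GenomicInterval("chr1", 200, 400), 2, "liver"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            consolidate_active(recs)

    def test_matches_per_base_oracle_on_random_tilings(self, rng):
        for _ in range(5):
            recs = random_tiling(rng, "liver")
            got = consolidate_active(recs)
            assert got == mask_runs(active_mask(recs))


class TestCombineTissues:
    def test_union_and_tissue_attribution(self):
        per_tissue = {
            "liver": [GenomicInterval("chr1", 100, 300)],
            "lung": [GenomicInterval("chr1", 250, 400)],
        }
        (re,) = combine_tissues(per_tissue)
        assert re.interval == GenomicInterval("chr1", 100, 400)
        assert re.active_tissues == {"liver", "lung"}
        assert not re.tissue_specific

    def test_single_tissue_flag(self):
        (re,) = combine_tissues({"liver": [GenomicInterval("chr1", 0, 100)], "lung": []})
        assert re.tissue_specific

    def test_matches_per_base_contributor_oracle(self, rng):
        tissues = [f"t{i}" for i in range(8)]
        per_tissue = {
            t: mask_runs(active_mask(random_tiling(rng, t))) for t in tissues
        }
        res = combine_tissues(per_tissue)
        masks = {t: np.zeros(CHROM_LEN, dtype=bool) for t in tissues}
        for t, ivs in per_tissue.items():
            for iv in ivs:
                masks[t][iv.start : iv.end] = True
        union = np.logical_or.reduce(list(masks.values()))
        assert [r.interval for r in res] == mask_runs(union)
        for r in res:
            contributors = {
                t for t in tissues if masks[t][r.interval.start : r.interval.end].any()
            }
            assert r.active_tissues == contributors

    def test_catalog_disjoint_and_base_conserving(self, rng):
        per_tissue = {
            f"t{i}": mask_runs(active_mask(random_tiling(rng, f"t{i}")))
            for i in range(4)
        }
        res = combine_tissues(per_tissue)
        ivs = sorted(r.interval for r in res)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end < b.start
        union = np.zeros(CHROM_LEN, dtype=bool)
        for t_ivs in per_tissue.values():
            for iv in t_ivs:
                union[iv.start : iv.end] = True
        assert sum(iv.length for iv in ivs) == int(union.sum())


def make_gene(gene_id, chrom, start, end, strand="+", biotype="protein_coding"):
    tss = start if strand == "+" else end - 1
    return GeneModel(gene_id, biotype, GenomicInterval(chrom, start, end), strand, (tss,))


class TestClassifyRe:
    def test_tss_proximal_window(self):
        gene = make_gene("g", "chr1", 10_000, 18_000)
        assert classify_re(GenomicInterval("chr1", 8_500, 9_200), [gene]) == "tss_proximal"
        # exactly 2 kb away on either side still counts (inclusive bound)
        assert classify_re(GenomicInterval("chr1", 7_000, 8_001), [gene]) == "tss_proximal"
        assert classify_re(GenomicInterval("chr1", 12_000, 12_400), [gene]) == "tss_proximal"

    def test_genic_far_from_tss(self):
        gene = make_gene("g", "chr1", 20_000, 60_000)
        assert classify_re(GenomicInterval("chr1", 50_000, 50_400), [gene]) == "genic"

    def test_excluded_near_noncoding_tss(self):
        nc = make_gene("nc", "chr1", 100_000, 105_000, biotype="non_coding")
        re = GenomicInterval("chr1", 97_900, 98_200)  # 1,900 bp from the TSS
        assert classify_re(re, [nc]) == "excluded"

    def test_excluded_near_unannotated_tss(self):
        re = GenomicInterval("chr1", 5_000, 5_400)
        assert classify_re(re, [], extra_tss=[("chr1", 6_000)]) == "excluded"

    def test_coding_proximity_beats_exclusion(self):
        coding = make_gene("c", "chr1", 10_000, 20_000)
        nc = make_gene("nc", "chr1", 9_000, 9_500, biotype="non_coding")
        re = GenomicInterval("chr1", 9_400, 9_800)  # near both TSSs
        assert classify_re(re, [coding, nc]) == "tss_proximal"

    def test_intergenic_default(self):
        gene = make_gene("g", "chr1", 0, 5_000)
        assert classify_re(GenomicInterval("chr1", 50_000, 50_500), [gene]) == "intergenic"

    def test_total_function_on_random_layout(self, rng):
        genes = []
        for i in range(30):
            start = int(rng.integers(0, CHROM_LEN - 10_000))
            genes.append(
                make_gene(
                    f"g{i}", "chr1", start, start + int(rng.integers(2_000, 9_000)),
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype="protein_coding" if rng.random() < 0.8 else "non_coding",
                )
            )
        extra = [("chr1", int(p)) for p in rng.integers(0, CHROM_LEN, 10)]
        for _ in range(200):
            s = int(rng.integers(0, CHROM_LEN - 2_000))
            cls = classify_re(GenomicInterval("chr1", s, s + 400), genes, extra)
            assert cls in ("tss_proximal", "genic", "intergenic", "excluded")


class TestOpenChromatinSupport:
    def _re(self, start, end, tissues):
        return RegulatoryElement(GenomicInterval("chr1", start, end), frozenset(tissues))

    def test_tissue_matched_rule(self):
        res = [self._re(100, 500, {"liver"})]
        frac, flags = open_chromatin_support(
            res, {"liver": [GenomicInterval("chr1", 400, 600)]}
        )
        assert flags == [True] and frac == 1.0
        frac, flags = open_chromatin_support(
            res, {"lung": [GenomicInterval("chr1", 400, 600)]}
        )
        assert flags == [False] and frac == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        tissues = [f"t{i}" for i in range(4)]
        res = []
        for _ in range(150):
            s = int(rng.integers(0, CHROM_LEN - 1_000))
            k = int(rng.integers(1, 5))
            active = frozenset(
                tissues[j] for j in rng.choice(4, size=k, replace=False)
            )
            res.append(RegulatoryElement(GenomicInterval("chr1", s, s + 500), active))
        peaks = {
            t: [
                GenomicInterval("chr1", int(s), int(s) + 300)
                for s in rng.integers(0, CHROM_LEN - 300, size=40)
            ]
            for t in tissues
        }
        frac, flags = open_chromatin_support(res, peaks)
        for re, flag in zip(res, flags):
            brute = any(
                min(re.interval.end, p.end) - max(re.interval.start, p.start) > 0
                for t in re.active_tissues
                for p in peaks[t]
            )
            assert flag == brute
        assert frac == pytest.approx(sum(flags) / len(flags))


class TestStateFeatureEnrichment:
    def test_state_exactly_on_features(self):
        features = [GenomicInterval("chr1", 1_000, 2_000)]
        seg = [SegmentationRecord(GenomicInterval("chr1", 1_000, 2_000), 3, "t")]
        enr = state_feature_enrichment(seg, features, genome_size=100_000)
        assert enr[3] == pytest.approx(100_000 / 1_000)

    def test_uniform_state_is_null(self):
        seg = [SegmentationRecord(GenomicInterval("chr1", 0, 100_000), 14, "t")]
        enr = state_feature_enrichment(
            seg, [GenomicInterval("chr1", 40_000, 60_000)], genome_size=100_000
        )
        assert enr[14] == pytest.approx(1.0)
        assert np.isnan(enr[1])  # absent state -> undefined sentinel

    def test_matches_per_base_crosstab_oracle(self, rng):
        seg = random_tiling(rng, "t")
        features = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 2_000)))
            for s in rng.integers(0, CHROM_LEN - 2_000, size=30)
        ]
        enr = state_feature_enrichment(seg, features, genome_size=CHROM_LEN)
        fmask = np.zeros(CHROM_LEN, dtype=bool)
        for iv in features:
            fmask[iv.start : iv.end] = True
        state_arr = np.zeros(CHROM_LEN, dtype=np.int8)
        for r in seg:
            state_arr[r.interval.start : r.interval.end] = r.state
        background = fmask.sum() / CHROM_LEN
        for s in range(1, 15):
            in_state = state_arr == s
            if not in_state.any():
                assert np.isnan(enr[s])
                continue
            oracle = (fmask[in_state].mean()) / background
            assert enr[s] == pytest.approx(oracle, abs=1e-12)
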