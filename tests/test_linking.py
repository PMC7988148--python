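"""TMM normalization, expression flags, TAD assignment and link prediction."""

import dataclasses
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from recat.annotate import RegulatoryElement
from recat.intervals import GeneModel, GenomicInterval
from recat.linking import (
    NormalizedMatrix,
    assign_to_tads,
    expressed_and_specific,
    naive_pairs,
    predict_links,
    tmm_factors,
    variance_filter,
)
from recat.simulate import SimConfig, Simulation
from recat.tads import Tad


def counts_frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"f{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestTmm:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 500, size=200)
        df = counts_frame(np.column_stack([col] * 4))
        np.testing.assert_allclose(tmm_factors(df).to_numpy(), 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed_by_libsize(self, rng):
        col = rng.integers(1, 500, size=300)
        df = counts_frame(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_factors(df).to_numpy(), 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        df = counts_frame(rng.integers(0, 2_000, size=(400, 6)))
        f = tmm_factors(df).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_composition_bias_recentered(self, rng):
        # sample 2 = sample 1 with 10% of rows inflated 8-fold; after TMM the
        # unperturbed rows' median log-ratio must return to ~0.  The inflated
        # sample's effective library must shrink relative to its raw total,
        # i.e. its factor moves below the unperturbed sample's (factors scale
        # the library in the CPM denominator).
        base = rng.integers(50, 2_000, size=1_000)
        perturbed = base.copy()
        hot = rng.choice(1_000, size=100, replace=False)
        perturbed[hot] = perturbed[hot] * 8
        df = counts_frame(np.column_stack([base, perturbed]))
        f = tmm_factors(df)
        assert f.iloc[1] < f.iloc[0]
        lib = df.sum(axis=0)
        cpm = df / (lib * f) * 1e6
        cold = np.setdiff1d(np.arange(1_000), hot)
        log_ratio = np.log2(cpm.iloc[cold, 1] / cpm.iloc[cold, 0])
        assert abs(np.median(log_ratio)) <= 0.05

    def test_permutation_equivariance(self, rng):
        df = counts_frame(rng.integers(0, 1_000, size=(300, 5)))
        f = tmm_factors(df)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        f_perm = tmm_factors(df[perm])
        np.testing.assert_allclose(f_perm.to_numpy(), f[perm].to_numpy(), atol=1e-12)

    def test_zero_library_rejected(self):
        df = counts_frame([[0, 5], [0, 7]])
        with pytest.raises(ValueError, match="zero library"):
            tmm_factors(df)

    def test_matches_edger_oracle(self, rng, tmp_path):
        """Independent cross-check against edgeR's calcNormFactors."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the edgeR oracle")
        counts = rng.negative_binomial(5, 0.01, size=(500, 4))
        df = counts_frame(counts)
        csv = tmp_path / "counts.csv"
        df.to_csv(csv)
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.csv("{csv}", row.names=1))\n'
            'f <- calcNormFactors(DGEList(counts=x), method="TMM")$samples$norm.factors\n'
            'cat(sprintf("%.10f", f), sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.split()])
        got = tmm_factors(df).to_numpy()
        np.testing.assert_allclose(got, expected, rtol=2e-2)

    def test_cpm_identity(self, rng):
        df = counts_frame(rng.integers(0, 1_000, size=(100, 4)))
        nm = NormalizedMatrix(df)
        manual = df / (df.sum(axis=0) * nm.factors) * 1e6
        pd.testing.assert_frame_equal(nm.cpm, manual)


class TestExpressionFlags:
    def _flags(self, tissue_cpms):
        # one replicate per tissue keeps tissue means equal to the inputs
        df = pd.DataFrame(
            [v for v in tissue_cpms],
            index=[f"g{i}" for i in range(len(tissue_cpms))],
            columns=["a_r1", "b_r1", "c_r1"],
        )
        tmap = {"a_r1": "a", "b_r1": "b", "c_r1": "c"}
        return expressed_and_specific(df, tmap)

    def test_specific_at_fourfold(self):
        flags = self._flags([[40, 5, 5], [16, 5, 4], [0.9, 0.1, 0.2]])
        assert flags.loc["g0", "tissue_specific"]
        assert not flags.loc["g1", "tissue_specific"]  # 16/5 = 3.2 < 4
        assert flags.loc["g0", "expressed"]
        assert not flags.loc["g2", "expressed"]  # max CPM 0.9 < 1

    def test_zero_elsewhere_counts_as_specific(self):
        flags = self._flags([[3, 0, 0]])
        assert flags.loc["g0", "tissue_specific"]

    def test_replicates_averaged_per_tissue(self):
        df = pd.DataFrame(
            [[8.0, 0.0, 1.0, 1.0]], index=["g0"], columns=["a_r1", "a_r2", "b_r1", "b_r2"]
        )
        tmap = {"a_r1": "a", "a_r2": "a", "b_r1": "b", "b_r2": "b"}
        flags = expressed_and_specific(df, tmap)
        assert flags.loc["g0", "tissue_specific"]  # tissue means 4 vs 1


class TestVarianceFilter:
    def test_ratio_rule(self):
        df = counts_frame([[1, 7], [2, 10], [0, 3], [0, 0], [1, 6]])
        kept = set(variance_filter(df))
        assert kept == {"f0", "f2"}  # 7>6 kept; 5<=6 dropped; 0->3 kept; 6==6 dropped


def make_re(chrom, start, end, re_class="intergenic"):
    return RegulatoryElement(GenomicInterval(chrom, start, end), frozenset({"liver"}), re_class)


def make_gene(gid, chrom, start, end, strand="+", biotype="protein_coding"):
    tss = start if strand == "+" else end - 1
    return GeneModel(gid, biotype, GenomicInterval(chrom, start, end), strand, (tss,))


class TestAssignToTads:
    def test_boundary_conventions(self):
        tads = [Tad(GenomicInterval("chr1", 1_000, 2_000))]
        res = [make_re("chr1", 900, 1_100)]  # midpoint 1000 = TAD start
        genes = [make_gene("g1", "chr1", 1_990, 4_000)]  # TSS 1990 inside
        genes.append(make_gene("g2", "chr1", 2_000, 4_000))  # TSS 2000 = TAD end
        membership = assign_to_tads(res, genes, tads, re_ids=["r0"])
        assert membership[0] == (["r0"], ["g1"])

    def test_matches_bruteforce_oracle(self, rng):
        tads = []
        pos = 0
        for _ in range(20):
            pos += int(rng.integers(1_000, 5_000))
            end = pos + int(rng.integers(2_000, 10_000))
            tads.append(Tad(GenomicInterval("chr1", pos, end)))
            pos = end
        res, genes = [], []
        for i in range(100):
            s = int(rng.integers(0, pos))
            res.append(make_re("chr1", s, s + int(rng.integers(100, 1_000))))
            gs = int(rng.integers(0, pos))
            genes.append(make_gene(f"g{i}", "chr1", gs, gs + int(rng.integers(500, 3_000))))
        ids = [f"r{i}" for i in range(100)]
        membership = assign_to_tads(res, genes, tads, re_ids=ids)
        for ti, t in enumerate(tads):
            exp_res = [
                rid
                for rid, re in zip(ids, res)
                if t.interval.start <= re.interval.midpoint < t.interval.end
            ]
            exp_genes = [
                g.gene_id
                for g in genes
                if t.interval.start <= g.tss_5prime < t.interval.end
            ]
            assert membership[ti] == (exp_res, exp_genes)


class TestNaivePairs:
    def test_genic_re_inside_two_overlapping_genes(self):
        genes = [
            make_gene("gA", "chr1", 0, 10_000),
            make_gene("gB", "chr1", 4_000, 14_000),
        ]
        res = [make_re("chr1", 5_000, 5_500, re_class="genic")]
        assert naive_pairs(res, genes, re_ids=["r0"]) == {("r0", "gA"), ("r0", "gB")}

    def test_equidistant_tie_lexicographic(self):
        genes = [
            make_gene("gB", "chr1", 0, 1_000, strand="-"),     # TSS 999
            make_gene("gA", "chr1", 10_001, 11_000),          # TSS 10001
        ]
        res = [make_re("chr1", 5_200, 5_801)]  # edges 5200/5800: both TSS 4201 bp? no:
        # distances: |999-5200| = 4201, |10001-5800| = 4201 -> tie -> gA
        assert naive_pairs(res, genes, re_ids=["r0"]) == {("r0", "gA")}

    def test_matches_bruteforce_nearest_scan(self, rng):
        genes = []
        for i in range(40):
            s = int(rng.integers(0, 200_000))
            genes.append(make_gene(f"g{i:02d}", "chr1", s, s + int(rng.integers(500, 4_000))))
        res, ids = [], []
        for i in range(60):
            s = int(rng.integers(0, 200_000))
            res.append(make_re("chr1", s, s + 300))
            ids.append(f"r{i}")
        got = naive_pairs(res, genes, re_ids=ids)
        for rid, re in zip(ids, res):
            best = None
            for g in genes:
                for tss in g.tss_list:
                    if re.interval.contains(tss):
                        d = 0
                    else:
                        d = min(abs(tss - re.interval.start), abs(tss - (re.interval.end - 1)))
                    cand = (d, g.gene_id)
                    if best is None or cand < best:
                        best = cand
            assert (rid, best[1]) in got
            assert sum(1 for a, _ in got if a == rid) == 1


class TestPredictLinks:
    def _constant_matrix(self, ids, samples, value=100):
        return pd.DataFrame(value, index=ids, columns=samples)

    def test_single_tracking_pair_recovered_exactly(self):
        samples = [f"t{i}_r1" for i in range(8)]
        track = np.array([10, 25, 40, 80, 160, 320, 640, 1_280])
        # balancing rows sit outside the TAD and equalize library sizes, so
        # CPM of the constant rows stays constant (zero variance -> skipped)
        sig = self._constant_matrix(["r0", "r1", "rBal"], samples).astype(float)
        exp = self._constant_matrix(["gA", "gB", "gBal"], samples).astype(float)
        sig.loc["r0"] = track
        sig.loc["rBal"] = 2_000 - track
        exp.loc["gA"] = track * 3
        exp.loc["gBal"] = 6_000 - track * 3
        tads = [Tad(GenomicInterval("chr1", 0, 100_000))]
        res = [
            make_re("chr1", 1_000, 1_400),
            make_re("chr1", 2_000, 2_400),
            make_re("chr1", 500_000, 500_400),
        ]
        genes = [
            make_gene("gA", "chr1", 10_000, 13_000),
            make_gene("gB", "chr1", 20_000, 23_000),
            make_gene("gBal", "chr1", 600_000, 603_000),
        ]
        links, summary = predict_links(
            NormalizedMatrix(sig), NormalizedMatrix(exp), tads, res, genes,
            re_ids=["r0", "r1", "rBal"],
        )
        assert list(zip(links.re_id, links.gene_id)) == [("r0", "gA")]
        assert summary["n_skipped_zero_variance"] > 0

    def test_sample_column_mismatch_rejected(self):
        a = NormalizedMatrix(self._constant_matrix(["r0"], ["s1", "s2", "s3", "s4"], 5))
        cols = ["s1", "s2", "s3", "x4"]
        b = NormalizedMatrix(self._constant_matrix(["g0"], cols, 5))
        with pytest.raises(ValueError, match="sample columns"):
            predict_links(a, b, [], [], [], re_ids=[])

    def test_retained_subset_of_universe_with_q_below_alpha(self, small_sim):
        genes_df, res_df = small_sim.expression_and_signal()
        links, summary = _run_linking(small_sim, genes_df, res_df)
        assert (links["qvalue"] < 0.05).all()
        assert (links["rho"] > 0).all()
        assert len(links) <= summary["n_tests"]

    def test_sensitivity_monotone_in_link_rho(self):
        sens = []
        for rho in (0.9, 0.5, 0.25):
            vals = []
            for seed in (3, 4, 5):
                cfg = dataclasses.replace(SimConfig(), seed=seed, link_rho=rho,
                                          n_res=300, n_genes=150, n_true_links=30)
                sim = Simulation(cfg)
                genes_df, res_df = sim.expression_and_signal()
                links, _ = _run_linking(sim, genes_df, res_df)
                found = set(zip(links.re_id, links.gene_id))
                vals.append(len(found & sim.truth.links) / len(sim.truth.links))
            sens.append(np.mean(vals))
        assert sens[0] >= sens[1] >= sens[2]


def _run_linking(sim, genes_df, res_df, alpha=0.05):
    sig = NormalizedMatrix(res_df)
    expr = NormalizedMatrix(genes_df)
    sig = NormalizedMatrix(sig.counts.loc[variance_filter(sig.cpm)])
    expr = NormalizedMatrix(expr.counts.loc[variance_filter(expr.cpm)])
    return predict_links(
        sig, expr, [Tad(t) for t in sim.truth.tads], sim.truth.res, sim.truth.genes,
        re_ids=sim.truth.re_ids, alpha=alpha,
    )
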