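"""Enhancer-to-gene linking by signal/expression correlation within TADs.

H3K27ac read counts per RE and gene expression counts are TMM-normalized
to CPM; low-variance rows (max/min ratio <= 6 across samples) are removed;
every (RE, gene) pair sharing a TAD is tested by Spearman correlation
across all samples; p-values are BH-adjusted once genome-wide and pairs
with q < alpha (and rho > 0 by default) are retained.  A naive baseline
pairs genic REs with the genes they overlap and intergenic REs with their
nearest TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import RegulatoryElement
from .intervals import GeneModel
from .stats import bh_adjust
from .tads import Tad

__all__ = [
    "NormalizedMatrix",
    "tmm_factors",
    "expressed_and_specific",
    "variance_filter",
    "assign_to_tads",
    "predict_links",
    "naive_pairs",
    "VARIANCE_RATIO_THRESHOLD",
]

VARIANCE_RATIO_THRESHOLD = 6.0  # max/min CPM ratio a row must exceed to be kept
TRIM_M = 0.30  # two-sided trim fraction on M-values (log ratios)
TRIM_A = 0.05  # two-sided trim fraction on A-values (log abundances)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, one per sample column.

    The reference sample is the one whose upper quartile of library-size-
    scaled counts (over rows with any positive count) is closest to the
    mean upper quartile.  For each sample vs the reference, rows positive
    in both contribute M = log2 ratio and A = mean log2 abundance; rows in
    the outer 30% tails of M or 5% tails of A are trimmed, and the factor
    is 2**(weighted mean of surviving M) with inverse asymptotic binomial
    variance weights.  Factors are scaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    values = counts.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    nonzero = values[(values > 0).any(axis=1)]
    uq = np.quantile(nonzero / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    y_r, n_r = values[:, ref], lib[ref]
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        y_k, n_k = values[:, k], lib[k]
        both = (y_k > 0) & (y_r > 0)
        yk, yr = y_k[both], y_r[both]
        m = np.log2((yk / n_k) / (yr / n_r))
        a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
        if len(m) == 0:
            continue
        lo_m, hi_m = np.quantile(m, [TRIM_M, 1 - TRIM_M])
        lo_a, hi_a = np.quantile(a, [TRIM_A, 1 - TRIM_A])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            continue
        var_term = (n_k - yk[keep]) / (n_k * yk[keep]) + (n_r - yr[keep]) / (n_r * yr[keep])
        w = 1.0 / np.maximum(var_term, 1e-12)  # guard degenerate one-row inputs
        factors[k] = 2.0 ** (float(np.sum(w * m[keep]) / np.sum(w)))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


@dataclass
class NormalizedMatrix:
    """Raw counts plus TMM factors and derived CPM values."""

    counts: pd.DataFrame
    lib_sizes: pd.Series = field(init=False)
    factors: pd.Series = field(init=False)
    cpm: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.lib_sizes = self.counts.sum(axis=0)
        self.factors = tmm_factors(self.counts)
        eff = self.lib_sizes * self.factors
        self.cpm = self.counts / eff * 1e6


def expressed_and_specific(
    cpm: pd.DataFrame, tissue_map: Mapping[str, str], fold: float = 4.0
) -> pd.DataFrame:
    """Per-row expressed and tissue-specific flags from tissue-mean CPM.

    Expressed: max tissue-level CPM >= 1.  Tissue-specific: some tissue is
    >= ``fold`` times every other tissue (a zero elsewhere counts as
    satisfied provided the top tissue is positive).
    """
    tissues = pd.Series({s: tissue_map[s] for s in cpm.columns})
    tissue_cpm = cpm.T.groupby(tissues).mean().T
    max_t = tissue_cpm.max(axis=1)
    expressed = max_t >= 1.0
    arr = tissue_cpm.to_numpy()
    order = np.argsort(arr, axis=1)
    top = arr[np.arange(len(arr)), order[:, -1]]
    second = arr[np.arange(len(arr)), order[:, -2]] if arr.shape[1] > 1 else np.zeros(len(arr))
    specific = (top > 0) & (top >= fold * second)
    return pd.DataFrame(
        {"expressed": expressed, "tissue_specific": specific}, index=cpm.index
    )


def variance_filter(
    values: pd.DataFrame, threshold: float = VARIANCE_RATIO_THRESHOLD
) -> pd.Index:
    """Rows whose max/min ratio across samples exceeds ``threshold``.

    Rows with min = 0 but max > 0 have infinite ratio and are retained;
    all-zero rows are dropped.
    """
    arr = values.to_numpy(dtype=float)
    mx = arr.max(axis=1)
    mn = arr.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mn > 0, mx / mn, np.where(mx > 0, np.inf, 0.0))
    return values.index[ratio > threshold]


def assign_to_tads(
    res: Sequence[RegulatoryElement],
    genes: Sequence[GeneModel],
    tads: Sequence[Tad],
    re_ids: Sequence[str] | None = None,
) -> dict[int, tuple[list[str], list[str]]]:
    """Per-TAD (RE ids, gene ids) membership.

    An RE belongs to a TAD when its midpoint lies in the TAD interval
    (half-open); a gene belongs when its 5'-most protein-coding TSS does.
    Elements outside every TAD join none.
    """
    if re_ids is None:
        re_ids = [f"RE{i:06d}" for i in range(len(res))]
    membership: dict[int, tuple[list[str], list[str]]] = {
        i: ([], []) for i in range(len(tads))
    }
    tad_list = [(i, t.interval) for i, t in enumerate(tads)]
    for rid, re in zip(re_ids, res):
        mid = re.interval.midpoint
        for i, tiv in tad_list:
            if tiv.chrom == re.interval.chrom and tiv.contains(mid):
                membership[i][0].append(rid)
                break
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        tss = g.tss_5prime
        for i, tiv in tad_list:
            if tiv.chrom == g.body.chrom and tiv.contains(tss):
                membership[i][1].append(g.gene_id)
                break
    return membership


def _rank_normalize(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise centered unit-norm rank vectors; flag rows w/o variance."""
    arr = df.to_numpy(dtype=float)
    ranks = sps.rankdata(arr, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    ok = norms > 0
    ranks[ok] /= norms[ok, None]
    return ranks, ok


def predict_links(
    signal: NormalizedMatrix,
    expr: NormalizedMatrix,
    tads: Sequence[Tad],
    res: Sequence[RegulatoryElement],
    genes: Sequence[GeneModel],
    re_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    positive_only: bool = True,
    naive: set[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Test all same-TAD (RE, gene) pairs and retain q < alpha links.

    ``signal`` rows are RE ids, ``expr`` rows gene ids; both must share the
    same sample columns.  Rows absent from the matrices (e.g. removed by
    the variance filter) simply form no pairs.  Returns the retained links
    (re_id, gene_id, tad_id, rho, pvalue, qvalue, is_naive_pair) and a
    summary dict; the summary also counts tests skipped for zero variance.
    """
    if list(signal.cpm.columns) != list(expr.cpm.columns):
        raise ValueError("signal and expression matrices have different sample columns")
    n = signal.cpm.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if re_ids is None:
        re_ids = [f"RE{i:06d}" for i in range(len(res))]
    membership = assign_to_tads(res, genes, tads, re_ids=re_ids)
    sig_ranks, sig_ok = _rank_normalize(signal.cpm)
    exp_ranks, exp_ok = _rank_normalize(expr.cpm)
    sig_pos = {rid: i for i, rid in enumerate(signal.cpm.index)}
    exp_pos = {gid: i for i, gid in enumerate(expr.cpm.index)}

    rows = []
    rhos = []
    skipped = 0
    for tad_id, (rids, gids) in membership.items():
        rids = [r for r in rids if r in sig_pos]
        gids = [g for g in gids if g in exp_pos]
        if not rids or not gids:
            continue
        ri = np.array([sig_pos[r] for r in rids])
        gi = np.array([exp_pos[g] for g in gids])
        rho_mat = sig_ranks[ri] @ exp_ranks[gi].T
        for a, rid in enumerate(rids):
            for b, gid in enumerate(gids):
                if not (sig_ok[ri[a]] and exp_ok[gi[b]]):
                    skipped += 1
                    continue
                rows.append((rid, gid, tad_id))
                rhos.append(rho_mat[a, b])
    rho_arr = np.clip(np.asarray(rhos, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_arr * np.sqrt((n - 2) / (1.0 - rho_arr**2))
    pvals = np.where(
        np.abs(rho_arr) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    )
    pvals = np.minimum(pvals, 1.0)
    qvals = bh_adjust(pvals) if len(pvals) else np.empty(0)

    naive = naive or set()
    links = pd.DataFrame(
        {
            "re_id": [r[0] for r in rows],
            "gene_id": [r[1] for r in rows],
            "tad_id": [r[2] for r in rows],
            "rho": rho_arr,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )
    links["is_naive_pair"] = [
        (rid, gid) in naive for rid, gid in zip(links["re_id"], links["gene_id"])
    ]
    keep = links["qvalue"] < alpha
    if positive_only:
        keep &= links["rho"] > 0
    retained = links[keep].reset_index(drop=True)

    summary = _summarize(retained, res, genes, re_ids, naive)
    summary["n_tests"] = len(links)
    summary["n_skipped_zero_variance"] = skipped
    return retained, summary


def _summarize(links, res, genes, re_ids, naive) -> dict:
    summary: dict = {"n_links": len(links)}
    summary["n_res_linked"] = links["re_id"].nunique() if len(links) else 0
    summary["n_genes_linked"] = links["gene_id"].nunique() if len(links) else 0
    if len(links):
        per_re = links.groupby("re_id").size()
        per_gene = links.groupby("gene_id").size()
        summary["mean_genes_per_re"] = float(per_re.mean())
        summary["median_genes_per_re"] = float(per_re.median())
        summary["mean_res_per_gene"] = float(per_gene.mean())
        summary["median_res_per_gene"] = float(per_gene.median())
    cls = {rid: re.re_class for rid, re in zip(re_ids, res)}
    link_pairs = set(zip(links["re_id"], links["gene_id"])) if len(links) else set()
    for group in ("genic", "intergenic"):
        ids = [rid for rid in links["re_id"].unique() if cls.get(rid) == group] if len(links) else []
        if not ids:
            summary[f"frac_{group}_res_targeting_naive"] = float("nan")
            continue
        hit = sum(
            1
            for rid in ids
            if any((rid, gid) in naive for _, gid in _pairs_of(link_pairs, rid))
        )
        summary[f"frac_{group}_res_targeting_naive"] = hit / len(ids)
    return summary


def _pairs_of(pairs: set[tuple[str, str]], rid: str):
    return [p for p in pairs if p[0] == rid]


def naive_pairs(
    res: Sequence[RegulatoryElement],
    genes: Sequence[GeneModel],
    re_ids: Sequence[str] | None = None,
) -> set[tuple[str, str]]:
    """Baseline pairing: genic RE -> every overlapped gene; intergenic RE ->
    gene with nearest TSS (ties: smaller distance, then lexicographic id)."""
    if re_ids is None:
        re_ids = [f"RE{i:06d}" for i in range(len(res))]
    pairs: set[tuple[str, str]] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    for rid, re in zip(re_ids, res):
        chrom_genes = by_chrom.get(re.interval.chrom, [])
        if re.re_class == "genic":
            for g in chrom_genes:
                if re.interval.overlaps(g.body):
                    pairs.add((rid, g.gene_id))
        elif re.re_class == "intergenic":
            best: tuple[int, str] | None = None
            for g in chrom_genes:
                for tss in g.tss_list:
                    if re.interval.contains(tss):
                        d = 0
                    else:
                        d = min(abs(tss - re.interval.start), abs(tss - (re.interval.end - 1)))
                    cand = (d, g.gene_id)
                    if best is None or cand < best:
                        best = cand
            if best is not None:
                pairs.add((rid, best[1]))
    return pairs
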