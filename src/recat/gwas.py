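"""Overlap of GWAS SNPs with the RE catalog and per-category enrichment.

SNPs carry an association p-value and zero or more category labels
(geQTL, mQTL, sQTL, ...).  Each category is contrasted against the
*uncategorized* SNPs ("other") by Fisher's exact test on in-RE/out-RE
counts; SNPs with several categories count once in each.
"""

from __future__ import annotations

import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex
from .stats import fisher_exact_2x2

__all__ = [
    "read_snps",
    "write_snps",
    "flag_in_re",
    "pvalue_density",
    "category_enrichment",
]

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["chrom", "pos", "pvalue", "categories"]


def read_snps(path: str | os.PathLike) -> pd.DataFrame:
    """SNP TSV: chrom, pos (0-based), pvalue, semicolon-joined categories."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "pos": np.int64, "pvalue": float, "categories": str}
    )
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["categories"] = df["categories"].fillna("")
    if ((df["pvalue"] <= 0) | (df["pvalue"] > 1)).any():
        raise ValueError(f"{path}: SNP p-values must lie in (0, 1]")
    if (df["pos"] < 0).any():
        raise ValueError(f"{path}: negative SNP positions")
    return df


def write_snps(path: str | os.PathLike, snps: pd.DataFrame) -> None:
    snps.to_csv(path, sep="\t", index=False)


def flag_in_re(snps: pd.DataFrame, catalog: Sequence[GenomicInterval]) -> np.ndarray:
    """Boolean per SNP: position lies within some RE (half-open)."""
    index = IntervalIndex(catalog)
    flags = np.zeros(len(snps), dtype=bool)
    positional = snps.reset_index(drop=True)
    for chrom, group in positional.groupby("chrom", sort=False):
        flags[group.index.to_numpy()] = index.contains_points(
            str(chrom), group["pos"].to_numpy()
        )
    return flags


def pvalue_density(
    snps: pd.DataFrame, in_re: np.ndarray, bins: int = 50
) -> pd.DataFrame:
    """Normalized p-value histograms for in-RE vs out-of-RE SNPs.

    Equal-width bins on [0, 1]; each group's histogram sums to 1.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    p = snps["pvalue"].to_numpy()
    out = {}
    for label, mask in (("in_re", in_re), ("out_re", ~in_re)):
        counts, _ = np.histogram(p[mask], bins=edges)
        total = counts.sum()
        out[label] = counts / total if total else np.zeros(bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], **out}
    )


def _category_sets(categories: pd.Series) -> list[set[str]]:
    return [set(c.split(";")) - {""} for c in categories]


def category_enrichment(snps: pd.DataFrame, in_re: np.ndarray) -> pd.DataFrame:
    """Per-category in-RE fraction, ratio vs uncategorized, and Fisher p.

    The 2x2 table for category c is [[c & inRE, c & outRE],
    [other & inRE, other & outRE]] where "other" = SNPs with no category.
    Categories with zero SNPs are skipped (logged).
    """
    cat_sets = _category_sets(snps["categories"])
    all_cats = sorted(set().union(*cat_sets)) if cat_sets else []
    other_mask = np.array([not s for s in cat_sets], dtype=bool)
    o_in = int((other_mask & in_re).sum())
    o_out = int((other_mask & ~in_re).sum())
    frac_other = o_in / (o_in + o_out) if (o_in + o_out) else float("nan")
    rows = []
    for cat in all_cats:
        mask = np.array([cat in s for s in cat_sets], dtype=bool)
        c_in = int((mask & in_re).sum())
        c_out = int((mask & ~in_re).sum())
        if c_in + c_out == 0:
            logger.info("category %s has no SNPs; skipped", cat)
            continue
        frac = c_in / (c_in + c_out)
        odds, p = fisher_exact_2x2([[c_in, c_out], [o_in, o_out]])
        rows.append(
            {
                "category": cat,
                "n_snps": c_in + c_out,
                "frac_in_re": frac,
                "ratio_vs_other": frac / frac_other if frac_other else float("inf"),
                "odds_ratio": odds,
                "fisher_p": p,
            }
        )
    rows.append(
        {
            "category": "other",
            "n_snps": o_in + o_out,
            "frac_in_re": frac_other,
            "ratio_vs_other": 1.0,
            "odds_ratio": 1.0,
            "fisher_p": 1.0,
        }
    )
    return pd.DataFrame(rows)
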