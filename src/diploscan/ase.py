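"""Allele-specific expression testing, categorization and SV-proximity tests.

Per gene and tissue, the alternate-allele count is tested against a
balanced Binomial(total, 0.5) with a two-sided exact binomial test;
p-values are Benjamini-Hochberg adjusted within each tissue. The allelic
log ratio log2((alt + 0.01) / (ref + 0.01)) (the pseudocount only guards
the logarithm, it never enters the test) splits significant genes into
"complete" ASE (|log2fc| >= 5: one allele effectively silent) and
"partial" ASE. Distances from genes to their nearest large INDEL,
upstream and downstream, are compared between categories with two-sample
Kolmogorov-Smirnov tests.

The exact binomial is used rather than a count-model contrast because the
two allele counts of a gene share library and gene effects: conditional on
the total, the allelic split is the sufficient statistic.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import binomtest, ks_2samp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05
LFC_THRESHOLD = 5.0
PSEUDOCOUNT = 0.01
MIN_TOTAL = 10
MIN_KS_SAMPLE = 5

CATEGORIES = ("complete", "partial", "none")


# ------------------------------------------------------------------- testing


def test_ase(
    counts: pd.DataFrame,
    alpha: float = ALPHA,
    lfc_threshold: float = LFC_THRESHOLD,
    min_total: int = MIN_TOTAL,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per gene/tissue ASE test on a table with columns
    gene, tissue, refCount, altCount.

    Genes with refCount + altCount < ``min_total`` are excluded per tissue.
    Returns the table plus log2fc, p, padj (BH within tissue) and category.
    """
    df = counts.copy()
    df["total"] = df["refCount"] + df["altCount"]
    df = df[df["total"] >= min_total].reset_index(drop=True)
    if df.empty:
        logger.warning("no testable genes after the min_total filter")
        return df.assign(log2fc=[], p=[], padj=[], category=[])

    df["log2fc"] = np.log2((df["altCount"] + pseudocount) / (df["refCount"] + pseudocount))
    df["p"] = [
        binomtest(int(a), int(n), 0.5).pvalue if n > 0 else 1.0
        for a, n in zip(df["altCount"], df["total"])
    ]
    df["padj"] = np.nan
    for tissue, sub in df.groupby("tissue"):
        _, padj, _, _ = multipletests(sub["p"].to_numpy(), method="fdr_bh")
        df.loc[sub.index, "padj"] = padj
    sig = df["padj"] < alpha
    df["category"] = np.where(
        sig & (df["log2fc"].abs() >= lfc_threshold),
        "complete",
        np.where(sig, "partial", "none"),
    )
    return df


def categorize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue fraction of tested genes in each ASE category."""
    rows = []
    for tissue, sub in results.groupby("tissue"):
        n = len(sub)
        frac = sub["category"].value_counts(normalize=True)
        rows.append(
            (
                tissue,
                n,
                float(frac.get("complete", 0.0)),
                float(frac.get("partial", 0.0)),
                float(frac.get("none", 0.0)),
                float(frac.get("complete", 0.0) + frac.get("partial", 0.0)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["tissue", "n_tested", "frac_complete", "frac_partial", "frac_none", "frac_significant"],
    )


def tissue_sharing(results: pd.DataFrame) -> dict:
    """Set algebra over per-tissue significant gene sets.

    Returns counts of genes significant in all tissues / in exactly one,
    and the set of genes with complete ASE in every tissue they were tested
    in (tested in all tissues).
    """
    tissues = results["tissue"].unique()
    sig_sets = {
        t: set(sub.loc[sub["category"] != "none", "gene"])
        for t, sub in results.groupby("tissue")
    }
    tested_all = set.intersection(
        *(set(sub["gene"]) for _, sub in results.groupby("tissue"))
    ) if len(tissues) else set()
    in_all = set.intersection(*sig_sets.values()) & tested_all if sig_sets else set()
    gene_hits = pd.concat(
        [pd.Series(sorted(s)) for s in sig_sets.values()], ignore_index=True
    ).value_counts() if any(sig_sets.values()) else pd.Series(dtype=int)
    exactly_one = set(gene_hits[gene_hits == 1].index)
    complete_sets = [
        set(sub.loc[sub["category"] == "complete", "gene"])
        for _, sub in results.groupby("tissue")
    ]
    complete_all = set.intersection(*complete_sets) & tested_all if complete_sets else set()
    return {
        "n_all_tissues": len(in_all),
        "n_exactly_one": len(exactly_one),
        "all_tissues": in_all,
        "exactly_one": exactly_one,
        "complete_all_tissues": complete_all,
    }


def gene_level_categories(results: pd.DataFrame) -> pd.Series:
    """Collapse per-tissue calls to one label per gene: "complete" when the
    gene shows complete ASE in every tissue it was tested in, "none" when it
    is significant nowhere, "partial" otherwise."""
    out = {}
    for gene, sub in results.groupby("gene"):
        cats = set(sub["category"])
        if cats == {"complete"}:
            out[gene] = "complete"
        elif cats == {"none"}:
            out[gene] = "none"
        else:
            out[gene] = "partial"
    return pd.Series(out, name="category")


# ----------------------------------------------------------------------- PCA


@dataclasses.dataclass
class PcaResult:
    coordinates: pd.DataFrame  # sample x (PC1, PC2)
    explained: np.ndarray  # explained-variance fractions


def _pca_2d(matrix: pd.DataFrame) -> PcaResult:
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    coords = pd.DataFrame(
        (u[:, :2] * s[:2]), index=matrix.index, columns=["PC1", "PC2"]
    )
    return PcaResult(coords, explained[:2])


def allelic_pca(results: pd.DataFrame, pseudocount: float = PSEUDOCOUNT) -> dict[str, PcaResult]:
    """Sample PCA computed twice: on variance-stabilized totals (shifted
    log2 of depth-normalized counts) and on the allelic log2fc matrix.

    Samples (tissues) are observations, genes features; genes observed in
    every sample are used. Requires >= 3 samples.
    """
    tissues = results["tissue"].unique()
    if len(tissues) < 3:
        raise ValueError("allelic_pca requires at least 3 samples")
    totals = results.pivot_table(index="tissue", columns="gene", values="total").dropna(axis=1)
    lib = totals.sum(axis=1)
    norm = totals.div(lib / lib.mean(), axis=0)
    vst = np.log2(norm + 1.0)
    lfc = results.pivot_table(index="tissue", columns="gene", values="log2fc").dropna(axis=1)
    return {"vst": _pca_2d(vst), "log2fc": _pca_2d(lfc)}


# --------------------------------------------------------------- KS proximity


@dataclasses.dataclass
class ProximityReport:
    table: pd.DataFrame  # direction, pair, n1, n2, D, p, skipped

    def pvalue(self, cat1: str, cat2: str, direction: str) -> float:
        sel = self.table[
            (self.table["pair"] == f"{cat1}_vs_{cat2}") & (self.table["direction"] == direction)
        ]
        return float(sel["p"].iloc[0])


def proximity_ks(
    gene_categories: pd.Series,
    distances: dict[str, pd.Series],
    min_sample: int = MIN_KS_SAMPLE,
) -> ProximityReport:
    """Two-sided two-sample Kolmogorov-Smirnov tests between the
    |nearest-INDEL-distance| samples of ASE category pairs, per direction.

    ``distances`` maps direction ("upstream"/"downstream") to a Series of
    signed distances indexed by gene (NaN = no qualifying INDEL, dropped).
    Pairs with fewer than ``min_sample`` genes on either side are skipped.
    """
    rows = []
    pairs = [("complete", "partial"), ("complete", "none"), ("partial", "none")]
    for direction, dist in distances.items():
        joined = pd.DataFrame({"distance": dist}).join(gene_categories.rename("category"), how="inner")
        joined = joined.dropna(subset=["distance"])
        for c1, c2 in pairs:
            s1 = joined.loc[joined["category"] == c1, "distance"].abs().to_numpy()
            s2 = joined.loc[joined["category"] == c2, "distance"].abs().to_numpy()
            if len(s1) < min_sample or len(s2) < min_sample:
                rows.append((direction, f"{c1}_vs_{c2}", len(s1), len(s2), np.nan, np.nan, True))
                continue
            res = ks_2samp(s1, s2, alternative="two-sided")
            rows.append((direction, f"{c1}_vs_{c2}", len(s1), len(s2), float(res.statistic), float(res.pvalue), False))
    return ProximityReport(
        pd.DataFrame(rows, columns=["direction", "pair", "n1", "n2", "D", "p", "skipped"])
    )
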