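"""ASE testing, categorization, tissue sharing, PCA, KS proximity."""

import numpy as np
import pandas as pd
import pytest

from diploscan import ase


def counts_df(rows):
    return pd.DataFrame(rows, columns=["gene", "tissue", "refCount", "altCount"])


# ------------------------------------------------------------------- testing


def test_balanced_gene_is_none():
    res = ase.test_ase(counts_df([("g", "leaf", 160, 160)]))
    assert res["p"].iloc[0] == 1.0
    assert res["log2fc"].iloc[0] == 0.0
    assert res["category"].iloc[0] == "none"


def test_extreme_gene_is_complete():
    res = ase.test_ase(counts_df([("g", "leaf", 5, 320)]))
    r = res.iloc[0]
    assert r["log2fc"] == pytest.approx(np.log2(320.01 / 5.01))
    assert abs(r["log2fc"] - 6.0) < 0.01
    assert r["padj"] < 1e-10
    assert r["category"] == "complete"


def test_significant_but_moderate_is_partial():
    res = ase.test_ase(counts_df([("g", "leaf", 100, 220)]))
    r = res.iloc[0]
    assert r["padj"] < 0.05
    assert abs(r["log2fc"]) < 5
    assert r["category"] == "partial"


def test_extreme_ratio_without_significance_is_none():
    # one 0/10 gene among 99 balanced ones: raw p ~0.002 but BH kills it
    rows = [(f"b{i}", "leaf", 160, 160) for i in range(99)] + [("x", "leaf", 10, 0)]
    res = ase.test_ase(counts_df(rows)).set_index("gene")
    x = res.loc["x"]
    assert abs(x["log2fc"]) > 5
    assert x["p"] < 0.05 < x["padj"]
    assert x["category"] == "none"


def test_min_total_filter_and_zero_counts():
    rows = [("low", "leaf", 4, 5), ("ok", "leaf", 100, 100)]
    res = ase.test_ase(counts_df(rows))
    assert list(res["gene"]) == ["ok"]
    # min_total=0 keeps the all-zero gene: p=1, log2fc=0, none
    res0 = ase.test_ase(counts_df([("z", "leaf", 0, 0)]), min_total=0)
    r = res0.iloc[0]
    assert r["p"] == 1.0 and r["log2fc"] == 0.0 and r["category"] == "none"
    empty = ase.test_ase(counts_df([("low", "leaf", 1, 1)]))
    assert empty.empty


def test_bh_monotone_and_within_tissue():
    rng = np.random.default_rng(5)
    rows = []
    for t in ("leaf", "root"):
        for i in range(50):
            n = 200
            a = int(rng.binomial(n, 0.5))
            rows.append((f"g{i}", t, n - a, a))
    res = ase.test_ase(counts_df(rows))
    assert (res["padj"] >= res["p"] - 1e-12).all()
    assert (res["padj"] <= 1.0).all()
    # BH is applied within tissue: each tissue's padj is a function of its
    # own p-values only
    leaf = res[res["tissue"] == "leaf"]
    from statsmodels.stats.multitest import multipletests

    _, expected, _, _ = multipletests(leaf["p"].to_numpy(), method="fdr_bh")
    np.testing.assert_allclose(leaf["padj"].to_numpy(), expected)


def test_allele_swap_antisymmetry():
    rows = [("g1", "leaf", 30, 270), ("g2", "leaf", 150, 150), ("g3", "leaf", 200, 100)]
    swapped = [(g, t, a, r) for g, t, r, a in rows]
    res = ase.test_ase(counts_df(rows)).set_index("gene")
    res_s = ase.test_ase(counts_df(swapped)).set_index("gene")
    np.testing.assert_allclose(res["log2fc"], -res_s["log2fc"])
    np.testing.assert_allclose(res["p"], res_s["p"])
    assert (res["category"] == res_s["category"]).all()


def test_false_positive_rate_under_null():
    # balanced-truth genes: the fraction called significant stays near alpha
    rates = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(500):
            a = int(rng.binomial(200, 0.5))
            rows.append((f"g{i}", "leaf", 200 - a, a))
        res = ase.test_ase(counts_df(rows))
        rates.append((res["category"] != "none").mean())
    assert np.mean(rates) <= 0.05
    assert max(rates) <= 0.10


# -------------------------------------------------------- categorize/sharing


def _results(rows):
    return pd.DataFrame(rows, columns=["gene", "tissue", "category"])


def test_categorize_fractions():
    res = _results([
        ("g1", "leaf", "complete"), ("g2", "leaf", "partial"),
        ("g3", "leaf", "none"), ("g4", "leaf", "none"),
        ("g1", "root", "complete"), ("g2", "root", "complete"),
    ])
    cat = ase.categorize(res).set_index("tissue")
    assert cat.loc["leaf", "n_tested"] == 4
    assert cat.loc["leaf", "frac_complete"] == 0.25
    assert cat.loc["leaf", "frac_significant"] == 0.5
    assert cat.loc["root", "frac_complete"] == 1.0


def test_tissue_sharing_sets():
    res = _results([
        ("g1", "leaf", "complete"), ("g1", "root", "complete"),
        ("g2", "leaf", "partial"), ("g2", "root", "none"),
        ("g3", "leaf", "none"), ("g3", "root", "none"),
        ("g4", "leaf", "complete"), ("g4", "root", "partial"),
    ])
    sh = ase.tissue_sharing(res)
    assert sh["all_tissues"] == {"g1", "g4"}
    assert sh["n_all_tissues"] == 2
    assert sh["exactly_one"] == {"g2"}
    assert sh["complete_all_tissues"] == {"g1"}


def test_gene_level_categories_rules():
    res = _results([
        ("g1", "leaf", "complete"), ("g1", "root", "complete"),
        ("g2", "leaf", "none"), ("g2", "root", "none"),
        ("g3", "leaf", "complete"), ("g3", "root", "none"),
        ("g4", "leaf", "partial"), ("g4", "root", "partial"),
    ])
    levels = ase.gene_level_categories(res)
    assert levels["g1"] == "complete"
    assert levels["g2"] == "none"
    assert levels["g3"] == "partial"  # mixed
    assert levels["g4"] == "partial"


# ------------------------------------------------------------------------ PCA


def _pca_input(n_tissues=4, n_genes=40, ase_genes=(), ase_tissues=(), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_tissues):
        tissue = f"t{t}"
        for g in range(n_genes):
            total = 300
            if g in ase_genes and tissue in ase_tissues:
                ref, alt = 2, total - 2
            else:
                alt = int(rng.binomial(total, 0.5))
                ref = total - alt
            rows.append((f"g{g:03d}", tissue, ref, alt))
    return ase.test_ase(counts_df(rows), min_total=0)


def test_pca_requires_three_samples():
    res = _pca_input(n_tissues=2)
    with pytest.raises(ValueError, match="at least 3"):
        ase.allelic_pca(res)


def test_pca_explained_variance_bounds_and_shape():
    res = _pca_input()
    out = ase.allelic_pca(res)
    for key in ("vst", "log2fc"):
        pr = out[key]
        assert list(pr.coordinates.columns) == ["PC1", "PC2"]
        assert len(pr.coordinates) == 4
        assert 0.0 <= pr.explained.sum() <= 1.0 + 1e-9


def test_pca_separates_ase_cluster_on_log2fc_only():
    # two tissues with strong ASE on half the genes, two without; totals are
    # identical everywhere so only the allelic-ratio PCA separates them
    res = _pca_input(ase_genes=set(range(20)), ase_tissues={"t0", "t1"})
    out = ase.allelic_pca(res)
    lfc = out["log2fc"].coordinates["PC1"]
    g1, g2 = lfc[["t0", "t1"]], lfc[["t2", "t3"]]
    gap = min(g1.min(), g2.min()), max(g1.max(), g2.max())
    assert max(g1.max(), g2.max()) > 0  # non-degenerate
    assert (g1.max() < g2.min()) or (g2.max() < g1.min())  # clean split
    vst_spread = out["vst"].coordinates["PC1"].std()
    lfc_spread = lfc.std()
    assert lfc_spread > 5 * max(vst_spread, 1e-9)


def test_pca_duplicated_samples_coincide():
    res = _pca_input(ase_genes=set(range(10)), ase_tissues={"t0"})
    dup = res[res["tissue"] == "t0"].assign(tissue="t0b")
    res2 = pd.concat([res, dup], ignore_index=True)
    out = ase.allelic_pca(res2)
    coords = out["log2fc"].coordinates
    np.testing.assert_allclose(coords.loc["t0"], coords.loc["t0b"], atol=1e-8)


# ------------------------------------------------------------------------- KS


def test_proximity_identical_distances():
    cats = pd.Series({f"g{i}": ("complete" if i % 2 else "none") for i in range(40)})
    dist = pd.Series({f"g{i}": float(1000 + (i // 2) * 100) for i in range(40)})
    rep = ase.proximity_ks(cats, {"downstream": dist})
    assert rep.pvalue("complete", "none", "downstream") == pytest.approx(1.0)
    row = rep.table[(rep.table["pair"] == "complete_vs_none")].iloc[0]
    assert row["D"] == pytest.approx(0.0)


def test_proximity_small_sample_skipped():
    cats = pd.Series({"g1": "complete", "g2": "complete", "g3": "none",
                      "g4": "none", "g5": "none"})
    dist = pd.Series({g: 100.0 for g in cats.index})
    rep = ase.proximity_ks(cats, {"upstream": dist})
    row = rep.table[rep.table["pair"] == "complete_vs_none"].iloc[0]
    assert bool(row["skipped"])
    assert np.isnan(row["p"])


def test_proximity_nan_distances_dropped():
    cats = pd.Series({f"g{i}": ("complete" if i < 10 else "none") for i in range(20)})
    dist = pd.Series({f"g{i}": (np.nan if i < 7 else float(i)) for i in range(20)})
    rep = ase.proximity_ks(cats, {"downstream": dist})
    row = rep.table[rep.table["pair"] == "complete_vs_none"].iloc[0]
    assert row["n1"] == 3 and row["n2"] == 10
    assert bool(row["skipped"])  # 3 < min_sample


def test_proximity_null_calibration():
    # same distance distribution in both categories: p < 0.05 should be rare
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(60)]
        cats = pd.Series({g: ("complete" if i < 30 else "none") for i, g in enumerate(genes)})
        dist = pd.Series(rng.exponential(2000, 60), index=genes)
        rep = ase.proximity_ks(cats, {"downstream": dist})
        if rep.pvalue("complete", "none", "downstream") < 0.05:
            hits += 1
    assert hits <= 3


def test_proximity_detects_shift():
    genes = [f"g{i}" for i in range(60)]
    cats = pd.Series({g: ("complete" if i < 30 else "none") for i, g in enumerate(genes)})
    rng = np.random.default_rng(7)
    near = rng.uniform(100, 2000, 30)
    far = rng.uniform(20_000, 80_000, 30)
    dist = pd.Series(np.concatenate([near, far]), index=genes)
    rep = ase.proximity_ks(cats, {"downstream": dist})
    assert rep.pvalue("complete", "none", "downstream") < 1e-6
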