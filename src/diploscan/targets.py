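"""Reference-scale recovery targets computed from scratch.

Each function simulates a fresh synthetic diplome at the stated scale,
runs the corresponding analysis stage on it, and returns the recovered
quantity together with the sample size it was measured on. These are the
quantities a full-scale run of the workflow is expected to reproduce:

t5  heterozygosity (%) from the read k-mer profile, 1 Mb / 40x / k=21
t6  repetitive fraction (%) from the same profile
t7  haplotig/primary alignment divergence (%) over 50 independent 100 kb
    haplotype pairs (aligned-bp-weighted mean)
t8  mean per-tissue share (%) of genes with significant allele-specific
    expression, 2000 genes x 3 tissues at depth ~100
t9  Kolmogorov-Smirnov p-value comparing gene-to-nearest-INDEL distances
    of complete-ASE vs non-ASE genes (complete-ASE genes are simulated
    with a large INDEL within 5 kb)
"""

from __future__ import annotations

import numpy as np

from . import ase as ase_mod
from . import kmer as kmer_mod
from . import simulate as sim_mod
from . import svscan as sv_mod


def t5_t6_profile(seed: int, length: int = 1_000_000, k: int = 21):
    """(het_pct, repeat_pct, n_bases) recovered from a read k-mer profile."""
    cfg = sim_mod.tme7_preset(length, seed=seed, n_genes=0)
    genome = sim_mod.generate_diploid(cfg)
    reads = sim_mod.simulate_reads(genome)
    spectrum = kmer_mod.count_kmers(reads.sequences, k).spectrum()
    est = kmer_mod.profile_fit(spectrum)
    return float(est.het), float(100.0 - est.uniq), length


def t7_divergence(seed: int, n_pairs: int = 50, length: int = 100_000):
    """(divergence_pct, n_pairs): aligned-bp-weighted mean over fresh pairs."""
    num = 0.0
    den = 0
    for i in range(n_pairs):
        cfg = sim_mod.divergence_preset(seed=seed * 1000 + i, length=length)
        genome = sim_mod.generate_diploid(cfg)
        chains = sv_mod.anchor_align(genome.hapA, genome.hapB)
        rep = sv_mod.haplotype_divergence(chains, genome.hapA, genome.hapB)
        if rep.aligned_bp:
            num += rep.mean * rep.aligned_bp
            den += rep.aligned_bp
    return float(num / den), n_pairs


def t8_ase_significant(seed: int, n_genes: int = 2000, n_tissues: int = 3):
    """(significant_pct, n_tests): mean per-tissue share of significant genes."""
    cfg = sim_mod.SimConfig(
        haploid_length=12_000_000,
        het_snp_rate=0.0, small_indel_rate=0.0, repeat_fraction=0.0,
        sv_counts={}, n_genes=n_genes, n_tissues=n_tissues, seed=seed,
    )
    genome = sim_mod.generate_diploid(cfg)
    counts = sim_mod.simulate_allelic_counts(genome)
    results = ase_mod.test_ase(counts)
    fractions = ase_mod.categorize(results)
    return float(100.0 * fractions["frac_significant"].mean()), int(len(results))


def t9_proximity_p(seed: int, n_genes: int = 600):
    """(p_value, n_genes_compared) for complete-ASE vs non-ASE gene
    distances to the nearest large INDEL (best direction)."""
    n_indels = round(n_genes / 2 * 1.07)  # linked INDELs plus a free surplus
    cfg = sim_mod.SimConfig(
        haploid_length=12_000_000,
        het_snp_rate=0.0, small_indel_rate=0.0, repeat_fraction=0.0,
        sv_counts={"insertion": (n_indels + 1) // 2, "deletion": n_indels // 2},
        sv_size_range=(50, 5000),
        n_genes=n_genes, ase_complete_fraction=0.5, ase_partial_fraction=0.0,
        ase_sv_linked_fraction=1.0, seed=seed,
    )
    genome = sim_mod.generate_diploid(cfg)
    counts = sim_mod.simulate_allelic_counts(genome)
    gene_cats = ase_mod.gene_level_categories(ase_mod.test_ase(counts))
    genes = genome.genes.set_index("gene_id")
    indels = genome.truth_svs[genome.truth_svs["category"].isin(["insertion", "deletion"])][
        ["chrom", "start", "end"]
    ]
    distances = {
        d: sv_mod.distance_to_features(genes, indels, d)
        for d in ("upstream", "downstream")
    }
    report = ase_mod.proximity_ks(gene_cats, distances)
    rows = report.table[(report.table["pair"] == "complete_vs_none") & ~report.table["skipped"]]
    if rows.empty:
        return float("nan"), 0
    best = rows.loc[rows["p"].idxmin()]
    return float(best["p"]), int(best["n1"] + best["n2"])


def compute_all(seed: int) -> dict:
    """All targets from one master seed, as {"t5": {"value", "n"}, ...}."""
    rng = np.random.default_rng(seed)
    subs = rng.integers(1, 2**31 - 1, size=4)
    het, repeat_pct, n_bases = t5_t6_profile(int(subs[0]))
    div, n_pairs = t7_divergence(int(subs[1]))
    sig, n_tests = t8_ase_significant(int(subs[2]))
    p, n_genes = t9_proximity_p(int(subs[3]))
    return {
        "t5": {"value": het, "n": n_bases},
        "t6": {"value": repeat_pct, "n": n_bases},
        "t7": {"value": div, "n": n_pairs},
        "t8": {"value": sig, "n": n_tests},
        "t9": {"value": p, "n": n_genes},
    }
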