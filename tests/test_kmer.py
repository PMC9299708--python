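"""K-mer counting, profile fit, copy spectra, completeness/QV, rescue."""

import numpy as np
import pytest

from diploscan import kmer as km
from diploscan import simulate as sim
from conftest import random_dna

COMP = str.maketrans("ACGT", "TGCA")


def brute_force_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        canon = min(w, w.translate(COMP)[::-1])
        counts[canon] = counts.get(canon, 0) + 1
    return counts


# --------------------------------------------------------------- counting


def test_trivial_examples():
    s = km.count_kmers(["AAAA"], k=2).spectrum()
    assert s.hist == {3: 1}
    s = km.count_kmers(["ACGT"], k=4).spectrum()
    assert s.hist == {1: 1}
    store = km.count_kmers(["TTTT"], k=2)
    assert km.decode_kmer(int(store.codes[0]), 2) == "AA"


def test_brute_force_oracle_10kb(rng):
    seq = random_dna(rng, 10_000)
    k = 21
    store = km.count_kmers([seq], k=k)
    expected = brute_force_counts(seq, k)
    got = {km.decode_kmer(int(c), k): int(n) for c, n in zip(store.codes, store.counts)}
    assert got == expected
    # spectrum conservation: sum m*f(m) = window count
    spec = store.spectrum()
    assert spec.total_kmers == 10_000 - k + 1


def test_n_windows_skipped():
    store = km.count_kmers(["ACGTNACGTACGTACGTACGT"], k=5)
    expected = brute_force_counts("ACGTNACGTACGTACGTACGT", 5)
    got = {km.decode_kmer(int(c), 5): int(n) for c, n in zip(store.codes, store.counts)}
    assert got == expected


def test_empty_input_is_empty_store():
    store = km.count_kmers([], k=21)
    assert store.distinct_kmers == 0
    assert store.spectrum().hist == {}


def test_revcomp_canonical_involution(rng):
    k = 15
    codes = km.kmer_codes(km.encode_bases(random_dna(rng, 500)), k)
    assert np.array_equal(km.revcomp_codes(km.revcomp_codes(codes, k), k), codes)
    canon = km.canonical_codes(codes, k)
    assert np.array_equal(km.canonical_codes(canon, k), canon)
    for c in codes[:20]:
        s = km.decode_kmer(int(c), k)
        rc = s.translate(COMP)[::-1]
        assert km.decode_kmer(int(km.revcomp_codes(np.array([c], dtype=np.uint64), k)[0]), k) == rc


def test_merge_additivity(rng):
    a, b = random_dna(rng, 3000), random_dna(rng, 3000)
    merged = km.count_kmers([a], 21).merge(km.count_kmers([b], 21))
    direct = km.count_kmers([a, b], 21)
    assert np.array_equal(merged.codes, direct.codes)
    assert np.array_equal(merged.counts, direct.counts)


def test_spectrum_tsv_roundtrip(tmp_path, rng):
    spec = km.count_kmers([random_dna(rng, 2000)], 21).spectrum()
    p = tmp_path / "spec.tsv"
    spec.to_tsv(p)
    assert km.KmerSpectrum.from_tsv(p, k=21).hist == spec.hist


# --------------------------------------------------------------- profile fit


def test_profile_fit_homozygous_single_peak(rng):
    cfg = sim.SimConfig(haploid_length=120_000, het_snp_rate=0, small_indel_rate=0,
                        repeat_fraction=0, sv_counts={}, n_genes=0, seed=3)
    genome = sim.generate_diploid(cfg)
    reads = sim.simulate_reads(genome)
    spec = km.count_kmers(reads.sequences, 21).spectrum()
    est = km.profile_fit(spec, homozygous=True)
    assert est.het == 0.0
    # single peak at 2c; c is k-mer coverage 40 * (150 - 21 + 1) / 150 = 34.7
    assert abs(est.kcov - 34.7) < 4
    assert abs(est.len_bp - 120_000) / 120_000 < 0.07
    with pytest.raises(ValueError, match="no heterozygous peak"):
        km.profile_fit(spec)


# ----------------------------------------------------- copy spectra / QC


def test_copy_spectra_perfect_and_duplicated(genome200, reads200):
    read_store = km.count_kmers(reads200.sequences, 21)
    both = {**{f"A{k}": v for k, v in genome200.hapA.items()},
            **{f"B{k}": v for k, v in genome200.hapB.items()}}
    asm_store = km.count_kmers(both, 21)
    cs = km.copy_spectra(read_store, asm_store)
    est = km.profile_fit(read_store.spectrum())
    # perfect diploid assembly: no read k-mer above the noise cutoff is absent
    zero_row = cs.row_hist(0)
    assert sum(n for m, n in zero_row.items() if m >= est.m0) == 0
    # duplicating a contig shifts its k-mers one copy class upward
    name = next(iter(genome200.hapA))
    dup_store = asm_store.merge(km.count_kmers([genome200.hapA[name]], 21))
    cs2 = km.copy_spectra(read_store, dup_store)
    assert sum(cs2.row_hist(1).values()) < sum(cs.row_hist(1).values())


def test_completeness_qv_perfect(genome200, reads200):
    # random 40x reads: all reliable read k-mers present in a perfect assembly
    read_store = km.count_kmers(reads200.sequences, 21)
    asm = km.count_kmers(list(genome200.hapA.values()) + list(genome200.hapB.values()), 21)
    est = km.profile_fit(read_store.spectrum())
    qc = km.completeness_qv(read_store, asm, est.m0)
    assert qc.completeness == 100.0
    assert qc.missing_bp == 0
    # the QV cap needs reads that support every assembly k-mer, so use
    # end-to-end tiling reads instead of random sampling
    tiles = []
    for seq in list(genome200.hapA.values()) + list(genome200.hapB.values()):
        tiles.extend(seq[i : i + 150] for i in range(0, len(seq) - 149, 50))
        tiles.append(seq[-150:])
    tile_store = km.count_kmers(tiles, 21)
    qc2 = km.completeness_qv(tile_store, asm, 1)
    assert qc2.completeness == 100.0
    assert qc2.qv == 99.0  # capped


def test_completeness_drop_matches_set_difference(genome200, reads200):
    read_store = km.count_kmers(reads200.sequences, 21)
    est = km.profile_fit(read_store.spectrum())
    full = list(genome200.hapA.values()) + list(genome200.hapB.values())
    partial = [full[0][: len(full[0]) // 2], full[1]]
    asm = km.count_kmers(partial, 21)
    qc = km.completeness_qv(read_store, asm, est.m0)
    reliable = read_store.filter_min_count(est.m0)
    missing = reliable.missing_from(asm)
    expected = 100.0 * (1 - missing.distinct_kmers / reliable.distinct_kmers)
    assert qc.completeness == pytest.approx(expected)
    assert qc.completeness < 100.0


def test_qv_responds_to_errors(rng):
    seq = random_dna(rng, 50_000)
    reads = [seq[i : i + 150] for i in range(0, len(seq) - 150, 25)]
    read_store = km.count_kmers(reads, 21)
    # assembly with 1 error per 2000 bp
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for pos in range(1000, len(arr), 2000):
        arr[pos] = ord("A") if arr[pos] != ord("A") else ord("C")
    bad = arr.tobytes().decode()
    qc_good = km.completeness_qv(read_store, km.count_kmers([seq], 21), 2)
    qc_bad = km.completeness_qv(read_store, km.count_kmers([bad], 21), 2)
    assert qc_good.qv > qc_bad.qv
    # phred of 1/2000 error rate is ~33; allow generous factor-2 band
    assert 26 < qc_bad.qv < 40


def test_empty_assembly_errors(genome200, reads200):
    read_store = km.count_kmers(reads200.sequences[:100], 21)
    with pytest.raises(ValueError):
        km.completeness_qv(read_store, km.count_kmers([], 21), 3)


# ------------------------------------------------------- missing length


def test_missing_seq_estimate_arithmetic():
    assert km.missing_seq_estimate(km.KmerSpectrum(21, {100: 5000})) == 5000
    assert km.missing_seq_estimate(km.KmerSpectrum(21, {50: 1000, 100: 1000})) == 2000
    assert km.missing_seq_estimate(km.KmerSpectrum(21, {})) == 0


# ------------------------------------------------------------- rescue


def test_rescue_reads_from_withheld_segment(genome200):
    frag = sim.fragment_into_contigs(genome200, 25_000, drop_het_fraction=1.0)
    assert len(frag.withheld) > 0
    reads = sim.simulate_reads(genome200)
    read_store = km.count_kmers(reads.sequences, 21)
    asm_store = km.count_kmers(frag.all_contigs(), 21)
    est = km.profile_fit(read_store.spectrum())
    missing = read_store.filter_min_count(est.m0).missing_from(asm_store)
    rescued = km.rescue_reads(reads.sequences, missing)
    assert rescued
    # every rescued read really contains a missing k-mer (soundness)
    for seq in rescued[:200]:
        codes = km.canonical_codes(km.kmer_codes(km.encode_bases(seq), 21), 21)
        assert missing.contains(codes).any()
    # >=95% of hapB reads carrying a full k-mer window over a withheld truth
    # SNP are selected (reads between variants are homozygous by design and
    # cannot be rescued)
    chromB = next(iter(genome200.hapB))
    snp_b = np.sort(genome200.hapA_to_hapB_coord(
        genome200.truth_snps["chrom"].iloc[0],
        genome200.truth_snps["pos"].to_numpy(),
    ))
    rescued_set = set(rescued)
    n_target = n_hit = 0
    for seq, hap, chrom, start in zip(
        reads.sequences, reads.haplotype, reads.chrom, reads.start
    ):
        if hap != "B" or chrom != chromB or len(seq) < 150:
            continue
        lo = np.searchsorted(snp_b, start + 20, side="left")
        hi = np.searchsorted(snp_b, start + len(seq) - 21, side="right")
        if hi > lo:
            n_target += 1
            if seq in rescued_set:
                n_hit += 1
    assert n_target > 20
    assert n_hit / n_target >= 0.95


def test_rescue_empty_missing_set(reads200):
    empty = km.count_kmers([], 21)
    assert km.rescue_reads(reads200.sequences[:50], empty) == []


def test_filter_rescued_contigs_boundaries():
    contigs = [
        ("a", "A" * 10_000, 9.9),   # dropped: coverage below threshold
        ("b", "A" * 500, 10.0),     # kept: both thresholds inclusive
        ("c", "A" * 499, 50.0),     # dropped: too short
        ("d", "A" * 501, 10.1),     # kept
    ]
    kept = km.filter_rescued_contigs(contigs)
    assert [c[0] for c in kept] == ["b", "d"]
    brute = [c for c in contigs if c[2] >= 10 and len(c[1]) >= 500]
    assert kept == brute
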