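"""SV scanning: anchors, classification, divergence, summaries, distances."""

import edlib
import numpy as np
import pandas as pd
import pytest

from diploscan import simulate as sim
from diploscan import svscan as sv
from conftest import random_dna


def _plant(seq: str, pos: int, ref_len: int, alt: str) -> str:
    return seq[:pos] + alt + seq[pos + ref_len :]


# -------------------------------------------------------------- base cases


def test_identical_sequences_no_calls(rng):
    seq = random_dna(rng, 60_000)
    ref, qry = {"r": seq}, {"q": seq}
    chains = sv.anchor_align(ref, qry)
    best = sv.best_chain_per_query(chains)
    assert set(best) == {"q"}
    ch = best["q"]
    assert ch.strand == "+"
    # a single anchor spans (nearly) the whole sequence
    assert ch.matched_bp >= 60_000 - 50
    assert sv.call_svs(ref, qry) == []
    rep = sv.haplotype_divergence(chains, ref, qry)
    assert rep.mean == 0.0
    assert rep.aligned_bp >= 60_000 - 50


def test_empty_input_empty_chains():
    assert sv.anchor_align({}, {"q": "ACGT" * 100}) == []
    assert sv.call_svs({"r": "ACGT" * 100}, {}) == []


def test_strand_symmetry_revcomp_query(rng):
    seq = random_dna(rng, 40_000)
    qry_fwd = _plant(seq, 20_000, 3000, "")  # 3 kb deletion
    ref = {"r": seq}
    fwd = sv.call_svs(ref, {"q": qry_fwd})
    rev = sv.call_svs(ref, {"q": sim.revcomp(qry_fwd)})
    assert len(fwd) == len(rev) == 1
    f, r = fwd[0], rev[0]
    assert (f.category, f.size) == (r.category, r.size) == ("deletion", 3000)
    assert (f.ref_start, f.ref_end) == (r.ref_start, r.ref_end)
    assert f.strand == "+" and r.strand == "-"


# ------------------------------------------------------------ planted events


def test_planted_deletion_category_size_and_bin(rng):
    seq = random_dna(rng, 50_000)
    qry = _plant(seq, 25_000, 4110, "")
    recs = sv.call_svs({"r": seq}, {"q": qry})
    assert len(recs) == 1
    rec = recs[0]
    assert rec.category == "deletion"
    assert rec.size == 4110
    assert abs(rec.ref_start - 25_000) <= 25  # up to anchor-extension slop
    summ = sv.summarize_svs(recs)
    row = summ.table[(summ.table["category"] == "deletion") & (summ.table["bin"] == "500-10000")]
    assert int(row["count"].iloc[0]) == 1
    assert int(row["total_bp"].iloc[0]) == 4110


def test_planted_insertion(rng):
    seq = random_dna(rng, 50_000)
    ins = random_dna(rng, 777)
    qry = _plant(seq, 30_000, 0, ins)
    recs = sv.call_svs({"r": seq}, {"q": qry})
    assert [(r.category, r.size) for r in recs] == [("insertion", 777)]


def test_tandem_expansion_two_to_four_copies(rng):
    unit = random_dna(rng, 300)
    left, right = random_dna(rng, 20_000), random_dna(rng, 20_000)
    ref = {"r": left + unit * 2 + right}
    qry = {"q": left + unit * 4 + right}
    recs = sv.call_svs(ref, qry)
    assert [(r.category, r.size) for r in recs] == [("tandem_expansion", 600)]
    recs_c = sv.call_svs(qry, ref)  # reversed roles: contraction
    assert [(r.category, r.size) for r in recs_c] == [("tandem_contraction", 600)]


def test_repeat_expansion_two_to_five_copies(rng):
    # 2 -> 5 copies: anchor overlap ~ 2u while size = 3u, so the 10% tandem
    # rule rejects tandem and the call is a repeat expansion
    unit = random_dna(rng, 400)
    left, right = random_dna(rng, 20_000), random_dna(rng, 20_000)
    ref = {"r": left + unit * 2 + right}
    qry = {"q": left + unit * 5 + right}
    recs = sv.call_svs(ref, qry)
    assert [(r.category, r.size) for r in recs] == [("repeat_expansion", 1200)]
    recs_c = sv.call_svs(qry, ref)
    assert [(r.category, r.size) for r in recs_c] == [("repeat_contraction", 1200)]


def test_small_indel_not_called_but_tallied(rng):
    seq = random_dna(rng, 30_000)
    qry = _plant(seq, 15_000, 0, random_dna(rng, 10))
    ref_d, qry_d = {"r": seq}, {"q": qry}
    assert sv.call_svs(ref_d, qry_d) == []
    chains = sv.anchor_align(ref_d, qry_d)
    tally = sv.within_alignment_variants(list(sv.best_chain_per_query(chains).values()),
                                         ref_d, qry_d)
    assert tally.indel_bases == 10
    assert tally.snp_count == 0


def test_snp_count_recovery(rng):
    n, L = 1410, 100_000
    seq = random_dna(rng, L)
    # keep ends SNP-free so the chain anchors the full length
    pos = np.sort(rng.choice(np.arange(300, L - 300), size=n, replace=False))
    pos = pos[np.concatenate(([True], np.diff(pos) >= 3))]
    arr = list(seq)
    for p in pos:
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    ref_d, qry_d = {"r": seq}, {"q": "".join(arr)}
    chains = list(sv.best_chain_per_query(sv.anchor_align(ref_d, qry_d)).values())
    tally = sv.within_alignment_variants(chains, ref_d, qry_d)
    assert abs(tally.snp_count - pos.size) / pos.size < 0.02


# -------------------------------------------------------------- divergence


def test_divergence_arithmetic():
    st = sv.ChainStats(matched=900, mismatches=0, indel_bases=100,
                       small_indel_bases=100, snp_count=0, columns=1000)
    assert st.divergence == 10.0
    st2 = sv.ChainStats(matched=980, mismatches=15, indel_bases=5,
                        small_indel_bases=5, snp_count=15, columns=1000)
    assert st2.divergence == 2.0
    empty = sv.ChainStats(0, 0, 0, 0, 0, 0)
    assert empty.divergence == 0.0


def test_chain_stats_match_full_dp_oracle(rng):
    # well-separated planted edits: chain-local alignment must reproduce the
    # exact global edit distance
    seq = random_dna(rng, 5000)
    qry = seq
    edits = [(400, 1, "sub"), (1200, 0, "ins3"), (2100, 1, "sub"),
             (3000, 4, "del"), (3900, 1, "sub"), (4500, 1, "sub")]
    dist = 0
    for pos, ref_len, kind in sorted(edits, reverse=True):
        if kind == "sub":
            base = qry[pos]
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[base]
            qry = _plant(qry, pos, 1, alt)
            dist += 1
        elif kind == "ins3":
            qry = _plant(qry, pos, 0, random_dna(rng, 3))
            dist += 3
        else:
            qry = _plant(qry, pos, 4, "")
            dist += 4
    ref_d, qry_d = {"r": seq}, {"q": qry}
    [ch] = sv.best_chain_per_query(sv.anchor_align(ref_d, qry_d)).values()
    st = sv.align_chain_gaps(ch, seq, qry)
    oracle = edlib.align(qry, seq, mode="NW")["editDistance"]
    assert st.mismatches + st.indel_bases == oracle == dist


def test_divergence_report_weighted_mean(rng):
    # two haplotigs with different divergence: report mean is bp-weighted
    seq = random_dna(rng, 40_000)
    q1 = seq[:20_000]  # identical half: divergence 0
    half = list(seq[20_000:])
    # SNP every 150 bp (spacing must exceed the 100 bp minimum anchor)
    for p in range(200, len(half) - 200, 150):
        half[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[half[p]]
    q2 = "".join(half)
    ref_d = {"r": seq}
    qry_d = {"q1": q1, "q2": q2}
    rep = sv.haplotype_divergence(sv.anchor_align(ref_d, qry_d), ref_d, qry_d)
    per = rep.per_haplotig.set_index("query")
    assert per.loc["q1", "divergence"] == 0.0
    assert 0.55 < per.loc["q2", "divergence"] < 0.80  # 1/150 = 0.67%
    w = per["aligned_bp"].to_numpy(float)
    x = per["divergence"].to_numpy(float)
    assert rep.mean == pytest.approx(float(np.average(x, weights=w)))
    assert rep.aligned_bp == int(w.sum())


def test_divergence_empty_report():
    rep = sv.haplotype_divergence([], {}, {})
    assert rep.aligned_bp == 0
    assert np.isnan(rep.mean)


# ------------------------------------------------- recall on full genomes


def _match_truth(truth: pd.DataFrame, records: list[sv.SVRecord]):
    """Match calls to truth rows: same category, size within 10 bp, call
    inside [tract_start-300, max(tract_end, end)+300]."""
    hits = np.zeros(len(truth), dtype=bool)
    unmatched = []
    for rec in records:
        ok = False
        for i, t in enumerate(truth.itertuples()):
            lo = t.tract_start - 300
            hi = max(t.tract_end, t.end) + 300
            if (rec.category == t.category and abs(rec.size - t.size) <= 10
                    and lo <= rec.ref_start and rec.ref_end <= hi):
                hits[i] = True
                ok = True
                break
        if not ok:
            unmatched.append(rec)
    return hits, unmatched


@pytest.mark.parametrize("seed", [2, 3])
def test_recall_on_simulated_diplome(seed):
    counts = {c: 6 for c in sim.SV_CATEGORIES}
    cfg = sim.SimConfig(haploid_length=500_000, het_snp_rate=0.01,
                        small_indel_rate=0.001, repeat_fraction=0.3,
                        sv_counts=counts, n_genes=0, seed=seed)
    g = sim.generate_diploid(cfg)
    recs = sv.call_svs(g.hapA, g.hapB)
    hits, unmatched = _match_truth(g.truth_svs, recs)
    assert hits.mean() >= 0.9
    assert unmatched == []


# ----------------------------------------------------------------- summary


def test_summary_conservation_and_bin_boundary():
    def rec(cat, size):
        return sv.SVRecord(cat, size, "r", 0, size, "q", 0, size, "+")

    records = [rec("deletion", 499), rec("deletion", 500), rec("insertion", 50),
               rec("insertion", 10_000), rec("tandem_expansion", 777)]
    summ = sv.summarize_svs(records)
    n, bp = summ.grand_totals()
    assert n == len(records)
    assert bp == sum(r.size for r in records)
    t = summ.table.set_index(["category", "bin"])
    assert t.loc[("deletion", "50-500"), "count"] == 1  # 499 in lower bin
    assert t.loc[("deletion", "500-10000"), "count"] == 1  # 500 goes up
    assert t.loc[("insertion", "50-500"), "count"] == 1
    assert t.loc[("insertion", "500-10000"), "count"] == 1  # 10000 inclusive
    cat = summ.category_totals().set_index("category")
    assert cat.loc["deletion", "total_bp"] == 999


def test_summary_from_cells_and_tsv(tmp_path):
    cells = {
        ("insertion", "50-500"): (699, 110_936),
        ("insertion", "500-10000"): (348, 791_434),
    }
    summ = sv.SVSummary.from_cells(cells)
    assert summ.grand_totals() == (1047, 902_370)
    ct = summ.category_totals().set_index("category")
    assert int(ct.loc["insertion", "count"]) == 1047
    p = tmp_path / "summary.tsv"
    summ.to_tsv(p)
    back = pd.read_csv(p, sep="\t")
    assert int(back[back["category"] == "Total"]["count"].iloc[0]) == 1047


# ------------------------------------------------------- feature distances


def test_distance_trivial_cases():
    a = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200], "strand": ["+"]})
    b = pd.DataFrame({"chrom": ["c", "c"], "start": [300, 10], "end": [350, 50]})
    assert sv.distance_to_features(a, b, "downstream").iloc[0] == 100.0
    assert sv.distance_to_features(a, b, "upstream").iloc[0] == -50.0
    # minus strand flips which neighbour counts
    a_minus = a.assign(strand="-")
    assert sv.distance_to_features(a_minus, b, "downstream").iloc[0] == 50.0
    assert sv.distance_to_features(a_minus, b, "upstream").iloc[0] == -100.0
    with pytest.raises(ValueError):
        sv.distance_to_features(a, b, "sideways")


def test_distance_overlap_excluded_and_nan():
    a = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200], "strand": ["+"]})
    overlapping = pd.DataFrame({"chrom": ["c"], "start": [150], "end": [250]})
    assert np.isnan(sv.distance_to_features(a, overlapping, "downstream").iloc[0])
    other_chrom = pd.DataFrame({"chrom": ["d"], "start": [300], "end": [400]})
    assert np.isnan(sv.distance_to_features(a, other_chrom, "downstream").iloc[0])


def test_distance_all_pairs_oracle(rng):
    n_a, n_b = 30, 60
    a_start = rng.integers(0, 100_000, n_a)
    a = pd.DataFrame({"chrom": "c", "start": a_start,
                      "end": a_start + rng.integers(50, 2000, n_a),
                      "strand": np.where(rng.random(n_a) < 0.5, "+", "-")})
    b_start = rng.integers(0, 100_000, n_b)
    b = pd.DataFrame({"chrom": "c", "start": b_start,
                      "end": b_start + rng.integers(50, 2000, n_b)})
    down = sv.distance_to_features(a, b, "downstream")
    up = sv.distance_to_features(a, b, "upstream")
    for idx, row in a.iterrows():
        after = (b["start"] - row["end"])[b["start"] >= row["end"]]
        before = (row["start"] - b["end"])[b["end"] <= row["start"]]
        gap_after = float(after.min()) if len(after) else np.nan
        gap_before = float(before.min()) if len(before) else np.nan
        if row["strand"] == "+":
            exp_down, exp_up = gap_after, -gap_before
        else:
            exp_down, exp_up = gap_before, -gap_after
        np.testing.assert_equal(down.at[idx], exp_down)
        np.testing.assert_equal(up.at[idx], exp_up)
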