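"""Unique-anchor whole-genome alignment and structural-variant classification.

The aligner finds exact match anchors between two assemblies from seed
k-mers that occur exactly once in each sequence collection, merges seeds
into maximal exact matches, extends them base-wise (extension may run into
flanking repeat copies, which is what exposes tandem/repeat copy-number
changes as anchor overlaps), and chains them colinearly per
(reference, query, strand) by weighted longest-increasing-subsequence.

Between consecutive anchors of a chain, the gap-length difference
d = query_gap - ref_gap classifies the event:

* both gaps >= 0        -> insertion (d > 0) or deletion (d < 0)
* exactly one gap < 0   -> copy-number change; when the anchor overlap
                           matches |d| within 10% the extra/lost copies are
                           adjacent (tandem expansion/contraction),
                           otherwise repeat expansion/contraction
* both gaps < 0         -> ambiguous, skipped and flagged

Gaps up to 1 kb are base-aligned (banded edit distance) to call SNPs and
small (<50 bp) indels and to compute per-haplotig divergence =
(mismatches + indel bases) / aligned columns.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from . import io as dio
from .kmer import canonical_codes, encode_bases, kmer_codes_with_positions
from .simulate import revcomp

logger = logging.getLogger(__name__)

SEED_K = 21  # k for seed matching (not the profile k; anchors are >= min_seed)
N_SPLIT = 10  # sequences are split at runs of more than this many Ns

SV_BINS = (50, 500, 10_000)


# ------------------------------------------------------------------- records


@dataclasses.dataclass
class Chain:
    """A colinear chain of exact-match anchors.

    Query coordinates are kept in "chain frame": for strand '-' they refer
    to the reverse complement of the query; :meth:`query_interval` maps back
    to the original strand.
    """

    ref_id: str
    query_id: str
    strand: str
    ref_starts: np.ndarray
    ref_ends: np.ndarray
    q_starts: np.ndarray
    q_ends: np.ndarray
    ref_len: int
    query_len: int

    @property
    def n_anchors(self) -> int:
        return len(self.ref_starts)

    @property
    def matched_bp(self) -> int:
        return int((self.ref_ends - self.ref_starts).sum())

    def ref_span(self) -> tuple[int, int]:
        return int(self.ref_starts[0]), int(self.ref_ends[-1])

    def query_span_chainframe(self) -> tuple[int, int]:
        return int(self.q_starts[0]), int(self.q_ends[-1])

    def query_interval(self) -> tuple[int, int]:
        """Chain span on the original query strand."""
        a, b = self.query_span_chainframe()
        if self.strand == "-":
            return self.query_len - b, self.query_len - a
        return a, b

    def to_chainframe_query(self, pos: int) -> int:
        return self.query_len - pos if self.strand == "-" else pos


@dataclasses.dataclass
class ChainStats:
    """Base-level statistics of a chain (anchors + aligned gaps <= 1 kb)."""

    matched: int
    mismatches: int
    indel_bases: int  # all gap-run bases in base-aligned regions
    small_indel_bases: int  # gap runs < 50 bp only
    snp_count: int
    columns: int

    @property
    def divergence(self) -> float:
        return 100.0 * (self.mismatches + self.indel_bases) / self.columns if self.columns else 0.0


@dataclasses.dataclass
class SVRecord:
    category: str
    size: int
    ref_id: str
    ref_start: int
    ref_end: int
    query_id: str
    query_start: int
    query_end: int
    strand: str


@dataclasses.dataclass
class SmallVariantTally:
    snp_count: int
    indel_bases: int  # bases affected by indels < 50 bp


@dataclasses.dataclass
class DivergenceReport:
    per_haplotig: pd.DataFrame  # query, divergence, aligned_bp
    mean: float  # aligned-bp weighted
    sd: float
    aligned_bp: int


# ------------------------------------------------------------ anchor finding


def _split_at_n_runs(seq: str) -> list[tuple[int, str]]:
    """(offset, piece) list after splitting at runs of > N_SPLIT Ns."""
    pieces = []
    for m in re.finditer(rf"[^N]+(?:N{{1,{N_SPLIT}}}[^N]+)*", seq):
        pieces.append((m.start(), m.group(0)))
    return pieces


def _unique_canonical(seqs: dict[str, str], k: int) -> np.ndarray:
    """Sorted canonical k-mer codes occurring exactly once in the collection."""
    chunks = []
    for s in seqs.values():
        codes, _ = kmer_codes_with_positions(encode_bases(s), k)
        chunks.append(canonical_codes(codes, k))
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    allc = np.concatenate(chunks)
    u, c = np.unique(allc, return_counts=True)
    return u[c == 1]


def _seed_positions(seq: str, k: int, keep: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward codes + positions of k-mers whose canonical form is in *keep*."""
    codes, pos = kmer_codes_with_positions(encode_bases(seq), k)
    if codes.size == 0:
        return codes, pos
    canon = canonical_codes(codes, k)
    mask = np.isin(canon, keep, assume_unique=False)
    return codes[mask], pos[mask]


def _merge_diagonal_runs(rpos: np.ndarray, qpos: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """Merge seed matches into maximal runs: (rstart, qstart, length)."""
    if rpos.size == 0:
        return []
    diag = rpos - qpos
    order = np.lexsort((rpos, diag))
    rp, qp, dg = rpos[order], qpos[order], diag[order]
    breaks = np.nonzero((np.diff(dg) != 0) | (np.diff(rp) != 1))[0] + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [rp.size]))
    return [(int(rp[s]), int(qp[s]), int(rp[e - 1] - rp[s] + k)) for s, e in zip(starts, ends)]


def _extend_exact(ref: str, query: str, rs: int, qs: int, length: int) -> tuple[int, int, int]:
    """Extend an exact match in both directions (stops at mismatch or N)."""
    re_, qe = rs + length, qs + length
    while rs > 0 and qs > 0 and ref[rs - 1] == query[qs - 1] and ref[rs - 1] != "N":
        rs -= 1
        qs -= 1
    lr, lq = len(ref), len(query)
    while re_ < lr and qe < lq and ref[re_] == query[qe] and ref[re_] != "N":
        re_ += 1
        qe += 1
    return rs, qs, re_ - rs


class _FenwickMax:
    def __init__(self, n: int):
        self.n = n
        self.score = [float("-inf")] * (n + 1)
        self.idx = [-1] * (n + 1)

    def update(self, i: int, score: float, idx: int) -> None:
        i += 1
        while i <= self.n:
            if score > self.score[i]:
                self.score[i], self.idx[i] = score, idx
            i += i & -i

    def query(self, i: int) -> tuple[float, int]:
        best, bidx = float("-inf"), -1
        i += 1
        while i > 0:
            if self.score[i] > best:
                best, bidx = self.score[i], self.idx[i]
            i -= i & -i
        return best, bidx


def _chain_anchors(anchors: list[tuple[int, int, int]]) -> list[list[tuple[int, int, int]]]:
    """Best colinear chain (weighted LIS on start coordinates, weight =
    anchor length); returns [chain] or [] — one best chain per group."""
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a[0], a[1]))
    qstarts = sorted({a[1] for a in anchors})
    rank = {q: i for i, q in enumerate(qstarts)}
    fen = _FenwickMax(len(qstarts))
    best = [0.0] * len(anchors)
    pred = [-1] * len(anchors)
    i = 0
    n = len(anchors)
    while i < n:
        j = i
        while j < n and anchors[j][0] == anchors[i][0]:
            j += 1
        for t in range(i, j):  # query phase: strictly smaller rstart AND qstart
            r = rank[anchors[t][1]]
            sc, pidx = fen.query(r - 1) if r > 0 else (float("-inf"), -1)
            w = anchors[t][2]
            best[t] = w + (sc if sc > 0 else 0.0)
            pred[t] = pidx if sc > 0 else -1
        for t in range(i, j):
            fen.update(rank[anchors[t][1]], best[t], t)
        i = j
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = pred[end]
    chain.reverse()
    return [chain]


def anchor_align(
    ref_seqs: dict[str, str],
    query_seqs: dict[str, str],
    min_seed: int = 100,
    min_cluster: int = 500,
    seed_k: int = SEED_K,
) -> list[Chain]:
    """Align two sequence collections with unique exact-match anchors.

    Seeds are k-mers unique in both collections; merged diagonal runs are
    extended base-wise, anchors shorter than ``min_seed`` are dropped, and
    per (ref, query, strand) the best colinear chain is kept if its matched
    length reaches ``min_cluster``. Sequences are split at runs of more
    than 10 Ns before seeding. Empty inputs give an empty chain list.
    """
    if not ref_seqs or not query_seqs:
        return []
    ref_u = _unique_canonical(ref_seqs, seed_k)
    qry_u = _unique_canonical(query_seqs, seed_k)
    keep = ref_u[np.isin(ref_u, qry_u, assume_unique=True)]
    if keep.size == 0:
        return []

    # ref seed index over split pieces
    ref_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for rid, rseq in ref_seqs.items():
        codes_all, pos_all = [], []
        for off, piece in _split_at_n_runs(rseq):
            codes, pos = _seed_positions(piece, seed_k, keep)
            codes_all.append(codes)
            pos_all.append(pos + off)
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.uint64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        ref_index[rid] = (codes[order], pos[order])

    chains: list[Chain] = []
    for qid, qseq in query_seqs.items():
        per_rid_strand: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for strand in "+-":
            oriented = qseq if strand == "+" else revcomp(qseq)
            for off, piece in _split_at_n_runs(oriented):
                qcodes, qpos = _seed_positions(piece, seed_k, keep)
                if qcodes.size == 0:
                    continue
                qpos = qpos + off
                for rid, (rcodes, rpos) in ref_index.items():
                    idx = np.searchsorted(rcodes, qcodes)
                    idx_c = np.clip(idx, 0, max(rcodes.size - 1, 0))
                    hit = rcodes.size > 0
                    if not hit:
                        continue
                    m = rcodes[idx_c] == qcodes
                    if not m.any():
                        continue
                    runs = _merge_diagonal_runs(rpos[idx_c[m]], qpos[m], seed_k)
                    rseq = ref_seqs[rid]
                    seen = set()
                    out = per_rid_strand.setdefault((rid, strand), [])
                    for rs, qs, ln in runs:
                        ers, eqs, eln = _extend_exact(rseq, oriented, rs, qs, ln)
                        key = (ers - eqs, ers)
                        if key in seen:
                            continue
                        seen.add(key)
                        if eln >= min_seed:
                            out.append((ers, eqs, eln))

        for (rid, strand), anchors in per_rid_strand.items():
            for chain in _chain_anchors(anchors):
                matched = sum(a[2] for a in chain)
                if matched < min_cluster:
                    continue
                rs = np.array([a[0] for a in chain])
                qs = np.array([a[1] for a in chain])
                ln = np.array([a[2] for a in chain])
                chains.append(
                    Chain(
                        ref_id=rid, query_id=qid, strand=strand,
                        ref_starts=rs, ref_ends=rs + ln, q_starts=qs, q_ends=qs + ln,
                        ref_len=len(ref_seqs[rid]), query_len=len(qseq),
                    )
                )
    return chains


def best_chain_per_query(chains: Iterable[Chain]) -> dict[str, Chain]:
    """The single best (most matched bp) chain per query; when the best
    chains disagree on strand the majority (heavier) strand wins, flagged."""
    best: dict[str, Chain] = {}
    for ch in chains:
        cur = best.get(ch.query_id)
        if cur is None or ch.matched_bp > cur.matched_bp:
            if cur is not None and cur.strand != ch.strand:
                logger.warning("query %s has chains on both strands; keeping majority", ch.query_id)
            best[ch.query_id] = ch
    return best


# ------------------------------------------------------- base-level variants


def _parse_ext_cigar(cigar: str):
    for m in re.finditer(r"(\d+)([=XID])", cigar):
        yield int(m.group(1)), m.group(2)


def align_chain_gaps(
    chain: Chain,
    ref_seq: str,
    query_seq: str,
    max_gap: int = 1000,
    small_indel_max: int = 50,
) -> ChainStats:
    """Base-align inter-anchor gaps <= ``max_gap`` on both sides by banded
    edit distance; accumulate mismatch/indel statistics over the chain.
    Gaps larger than ``max_gap`` (or negative) are left unaligned and do
    not contribute columns."""
    oriented = query_seq if chain.strand == "+" else revcomp(query_seq)
    matched = chain.matched_bp
    mism = 0
    indel = 0
    small_indel = 0
    columns = matched
    for i in range(chain.n_anchors - 1):
        rg0, rg1 = int(chain.ref_ends[i]), int(chain.ref_starts[i + 1])
        qg0, qg1 = int(chain.q_ends[i]), int(chain.q_starts[i + 1])
        rgap, qgap = rg1 - rg0, qg1 - qg0
        # chance extension around an indel can run the anchors a few bases
        # past each other on one sequence; trim the overlap back into the
        # gap so the indel is still aligned and counted
        trim = -min(rgap, qgap)
        if 0 < trim < small_indel_max:
            rg0 -= trim
            qg0 -= trim
            rgap += trim
            qgap += trim
            matched -= trim
            columns -= trim
        if rgap < 0 or qgap < 0 or max(rgap, qgap) > max_gap:
            continue
        if rgap == 0 and qgap == 0:
            continue
        rsub = ref_seq[rg0:rg1]
        qsub = oriented[qg0:qg1]
        if not rsub:
            gl = len(qsub)
            indel += gl
            small_indel += gl if gl < small_indel_max else 0
            columns += gl
            continue
        if not qsub:
            gl = len(rsub)
            indel += gl
            small_indel += gl if gl < small_indel_max else 0
            columns += gl
            continue
        res = edlib.align(qsub, rsub, mode="NW", task="path")
        for ln, op in _parse_ext_cigar(res["cigar"]):
            columns += ln
            if op == "X":
                mism += ln
            elif op in "ID":
                indel += ln
                if ln < small_indel_max:
                    small_indel += ln
    return ChainStats(
        matched=matched, mismatches=mism, indel_bases=indel,
        small_indel_bases=small_indel, snp_count=mism, columns=columns,
    )


def within_alignment_variants(
    chains: Sequence[Chain],
    ref_seqs: dict[str, str],
    query_seqs: dict[str, str],
    max_gap: int = 1000,
) -> SmallVariantTally:
    """SNP count (mismatch columns) and bases affected by indels < 50 bp
    across the base-aligned gap regions of the given chains."""
    snps = 0
    indel = 0
    for ch in chains:
        st = align_chain_gaps(ch, ref_seqs[ch.ref_id], query_seqs[ch.query_id], max_gap=max_gap)
        snps += st.snp_count
        indel += st.small_indel_bases
    return SmallVariantTally(snp_count=snps, indel_bases=indel)


# ------------------------------------------------------------ classification


def classify_between_anchors(
    chain: Chain,
    min_size: int = 50,
    max_size: int = 10_000,
    tandem_tol: float = 0.10,
) -> list[SVRecord]:
    """Classify the events between consecutive anchors of one chain."""
    records: list[SVRecord] = []
    for i in range(chain.n_anchors - 1):
        r1e, r2s = int(chain.ref_ends[i]), int(chain.ref_starts[i + 1])
        q1e, q2s = int(chain.q_ends[i]), int(chain.q_starts[i + 1])
        rgap = r2s - r1e
        qgap = q2s - q1e
        d = qgap - rgap
        size = abs(d)
        if size < min_size or size > max_size:
            continue
        overlap = -min(rgap, qgap)
        if overlap < min_size:
            # non-negative gaps up to a few bp of chance extension slop:
            # a plain gap difference
            category = "insertion" if d > 0 else "deletion"
        elif rgap < 0 and qgap < 0 and -max(rgap, qgap) >= min_size:
            # genuinely overlapping on both sequences
            logger.debug(
                "ambiguous overlap on both sequences near %s:%d, skipped", chain.ref_id, r1e
            )
            continue
        else:
            # a real overlap on one sequence: a copy-number change; adjacent
            # copies (overlap ~ size) are tandem, otherwise dispersed repeat
            tandem = abs(overlap - size) <= tandem_tol * size
            if d > 0:
                category = "tandem_expansion" if tandem else "repeat_expansion"
            else:
                category = "tandem_contraction" if tandem else "repeat_contraction"
        ref_lo, ref_hi = min(r1e, r2s), max(r1e, r2s)
        q_lo, q_hi = min(q1e, q2s), max(q1e, q2s)
        if chain.strand == "-":
            q_lo, q_hi = chain.query_len - q_hi, chain.query_len - q_lo
        records.append(
            SVRecord(
                category=category, size=size,
                ref_id=chain.ref_id, ref_start=ref_lo, ref_end=ref_hi,
                query_id=chain.query_id, query_start=q_lo, query_end=q_hi,
                strand=chain.strand,
            )
        )
    return records


def call_svs(
    ref_seqs: dict[str, str],
    query_seqs: dict[str, str],
    min_size: int = 50,
    max_size: int = 10_000,
    min_seed: int = 100,
    min_cluster: int = 500,
) -> list[SVRecord]:
    """End-to-end SV calling: anchor alignment, best chain per query,
    between-anchor classification."""
    chains = anchor_align(ref_seqs, query_seqs, min_seed=min_seed, min_cluster=min_cluster)
    records: list[SVRecord] = []
    for ch in best_chain_per_query(chains).values():
        records.extend(classify_between_anchors(ch, min_size=min_size, max_size=max_size))
    return records


# -------------------------------------------------------------------- summary


@dataclasses.dataclass
class SVSummary:
    """Per category x size bin counts and affected bp, with grand totals."""

    table: pd.DataFrame  # category, bin, count, total_bp

    @classmethod
    def from_records(cls, records: Sequence[SVRecord], bins: Sequence[int] = SV_BINS) -> "SVSummary":
        """Bin rule: [bins[0], bins[1]) and [bins[1], bins[2]] — the shared
        boundary goes to the upper bin."""
        lo, mid, hi = bins
        cells = []
        from .simulate import SV_CATEGORIES

        for cat in SV_CATEGORIES:
            for blo, bhi, label in ((lo, mid, f"{lo}-{mid}"), (mid, hi, f"{mid}-{hi}")):
                sel = [
                    r for r in records
                    if r.category == cat and (blo <= r.size < bhi or (bhi == hi and r.size == hi))
                ]
                cells.append((cat, label, len(sel), sum(r.size for r in sel)))
        return cls(pd.DataFrame(cells, columns=["category", "bin", "count", "total_bp"]))

    @classmethod
    def from_cells(cls, cells: dict[tuple[str, str], tuple[int, int]]) -> "SVSummary":
        """Build a summary directly from printed per-bin (count, bp) cells."""
        rows = [(cat, b, int(n), int(bp)) for (cat, b), (n, bp) in cells.items()]
        return cls(pd.DataFrame(rows, columns=["category", "bin", "count", "total_bp"]))

    def category_totals(self) -> pd.DataFrame:
        return self.table.groupby("category", sort=False)[["count", "total_bp"]].sum().reset_index()

    def grand_totals(self) -> tuple[int, int]:
        return int(self.table["count"].sum()), int(self.table["total_bp"].sum())

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        n, bp = self.grand_totals()
        out.loc[len(out)] = ["Total", "", n, bp]
        out.to_csv(path, sep="\t", index=False)


def summarize_svs(records: Sequence[SVRecord], bins: Sequence[int] = SV_BINS) -> SVSummary:
    return SVSummary.from_records(records, bins=bins)


# ----------------------------------------------------------------- divergence


def haplotype_divergence(
    chains: Iterable[Chain],
    ref_seqs: dict[str, str],
    query_seqs: dict[str, str],
    max_gap: int = 1000,
) -> DivergenceReport:
    """Per-haplotig divergence over its single best chain, and the
    aligned-bp-weighted mean and standard deviation across haplotigs."""
    rows = []
    for qid, ch in best_chain_per_query(chains).items():
        st = align_chain_gaps(ch, ref_seqs[ch.ref_id], query_seqs[qid], max_gap=max_gap)
        if st.columns:
            rows.append((qid, st.divergence, st.columns))
    df = pd.DataFrame(rows, columns=["query", "divergence", "aligned_bp"])
    if df.empty:
        return DivergenceReport(df, float("nan"), float("nan"), 0)
    w = df["aligned_bp"].to_numpy(dtype=float)
    x = df["divergence"].to_numpy(dtype=float)
    mean = float(np.average(x, weights=w))
    sd = float(np.sqrt(np.average((x - mean) ** 2, weights=w)))
    return DivergenceReport(df, mean, sd, int(w.sum()))


# --------------------------------------------------------- feature distances


def distance_to_features(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    direction: str,
) -> pd.Series:
    """Signed distance from each A feature to the nearest non-overlapping B
    feature in the given direction relative to A's strand.

    Positive = downstream of A, negative = upstream (the ``-D a``
    convention); overlapping B are excluded; A with no qualifying B gets
    NaN. ``features_a`` needs chrom/start/end/strand (+ index or gene_id);
    ``features_b`` needs chrom/start/end.
    """
    if direction not in ("upstream", "downstream"):
        raise ValueError("direction must be 'upstream' or 'downstream'")
    out = pd.Series(np.nan, index=features_a.index, dtype=float)
    for chrom, asub in features_a.groupby("chrom"):
        bsub = features_b[features_b["chrom"] == chrom]
        if bsub.empty:
            continue
        b_starts = np.sort(bsub["start"].to_numpy())
        b_ends = np.sort(bsub["end"].to_numpy())
        for idx, a in asub.iterrows():
            # nearest B fully after A and fully before A
            i = np.searchsorted(b_starts, a["end"])
            gap_after = b_starts[i] - a["end"] if i < b_starts.size else None
            j = np.searchsorted(b_ends, a["start"], side="right") - 1
            gap_before = a["start"] - b_ends[j] if j >= 0 else None
            plus = a["strand"] != "-"
            if direction == "downstream":
                gap = gap_after if plus else gap_before
                out.at[idx] = float(gap) if gap is not None else np.nan
            else:
                gap = gap_before if plus else gap_after
                out.at[idx] = -float(gap) if gap is not None else np.nan
    return out


# ------------------------------------------------------------------ PAF glue


def chains_to_paf(
    chains: Iterable[Chain],
    ref_seqs: dict[str, str],
    query_seqs: dict[str, str],
    max_gap: int = 1000,
) -> list[dio.PafRecord]:
    """One PAF record per chain with base-level match statistics."""
    records = []
    for ch in chains:
        st = align_chain_gaps(ch, ref_seqs[ch.ref_id], query_seqs[ch.query_id], max_gap=max_gap)
        qs, qe = ch.query_interval()
        rs, re_ = ch.ref_span()
        matches = st.matched + max(st.columns - st.matched - st.mismatches - st.indel_bases, 0)
        records.append(
            dio.PafRecord(
                query=ch.query_id, query_len=ch.query_len, query_start=qs, query_end=qe,
                strand=ch.strand, target=ch.ref_id, target_len=ch.ref_len,
                target_start=rs, target_end=re_,
                matches=matches, block_len=max(st.columns, 1),
            )
        )
    return records


def sv_records_to_bed(records: Sequence[SVRecord]) -> list[dio.BedRecord]:
    return [
        dio.BedRecord(r.ref_id, r.ref_start, r.ref_end, r.category, str(r.size), r.strand)
        for r in records
    ]


def sv_records_to_vcf(records: Sequence[SVRecord]) -> list[dio.VcfLiteRecord]:
    return [
        dio.VcfLiteRecord(
            r.ref_id, r.ref_start, r.category, "-", "-",
            {"SVTYPE": r.category, "SVLEN": r.size, "END": r.ref_end},
        )
        for r in records
    ]
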