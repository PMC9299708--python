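"""Linkage-map marker alignment and genetic/physical collinearity.

SNP markers come with a genetic position (cM) within a linkage group and a
source position on a draft genome. A ~201 nt tag (100 nt flanks) is
extracted around each marker, locally aligned to the assembly under test,
and filtered at alignment length > 150 nt and identity > 95% (strict, as
printed). Markers are then unique (one hit), duplicate (several — a proxy
for residual sequence duplication) or unplaced. Per linkage group the
Spearman correlation between genetic position and physical hit midpoint
measures collinearity; |rho| is reported because contig/scaffold
orientation is arbitrary before scaffolding.
"""

from __future__ import annotations

import dataclasses
import logging

import edlib
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .kmer import canonical_codes, encode_bases, kmer_codes_with_positions
from .simulate import revcomp

logger = logging.getLogger(__name__)

FLANK = 100
MIN_TAG_HIT_LEN = 150  # strict >
MIN_TAG_IDENTITY = 95.0  # strict >
TAG_SEED_K = 21


# ------------------------------------------------------------- tag extraction


def extract_marker_tags(markers: pd.DataFrame, source: dict[str, str], flank: int = FLANK) -> pd.DataFrame:
    """Extract flank-padded tags around marker positions.

    ``markers`` columns: marker, linkage_group, cM, source_seq, source_pos
    (1-based, as in map files). Tags are source[pos-flank-1 : pos+flank]
    (201 nt when unclipped); clipping at sequence bounds is recorded.
    """
    rows = []
    for m in markers.itertuples():
        seq = source[m.source_seq]
        pos0 = m.source_pos - 1  # to 0-based
        start = max(0, pos0 - flank)
        end = min(len(seq), pos0 + flank + 1)
        rows.append((m.marker, m.source_seq, start, end, end - start < 2 * flank + 1, seq[start:end]))
    return pd.DataFrame(rows, columns=["marker", "source_seq", "tag_start", "tag_end", "clipped", "tag"])


# --------------------------------------------------------------- tag alignment


class _SeedIndex:
    """Concatenated k-mer index of an assembly for short-query seeding."""

    def __init__(self, seqs: dict[str, str], k: int = TAG_SEED_K):
        self.k = k
        self.names = list(seqs)
        self.seqs = seqs
        codes_all, pos_all, sid_all = [], [], []
        for si, name in enumerate(self.names):
            codes, pos = kmer_codes_with_positions(encode_bases(seqs[name]), k)
            codes_all.append(canonical_codes(codes, k))
            pos_all.append(pos)
            sid_all.append(np.full(pos.size, si, dtype=np.int32))
        self.codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.uint64)
        self.pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
        self.sid = np.concatenate(sid_all) if sid_all else np.empty(0, dtype=np.int32)
        order = np.argsort(self.codes, kind="stable")
        self.codes, self.pos, self.sid = self.codes[order], self.pos[order], self.sid[order]

    def hits(self, codes: np.ndarray, max_occ: int = 100):
        lo = np.searchsorted(self.codes, codes, side="left")
        hi = np.searchsorted(self.codes, codes, side="right")
        for qi, (a, b) in enumerate(zip(lo, hi)):
            if 0 < b - a <= max_occ:
                yield qi, self.pos[a:b], self.sid[a:b]


def _candidate_windows(tag_len: int, qpos, tpos, sids, seq_lens, band: int = 30):
    """Cluster seed hits by (sequence, diagonal band) into target windows."""
    clusters: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for q, t, s in zip(qpos, tpos, sids):
        dband = (t - q) // band
        for db in (dband - 1, dband, dband + 1):
            clusters.setdefault((s, db), []).append((q, t))
    windows = {}
    for (s, _), pts in clusters.items():
        tmin = min(t - q for q, t in pts)
        lo = max(0, tmin - band)
        hi = min(seq_lens[s], tmin + tag_len + band)
        windows[(s, lo)] = max(windows.get((s, lo), 0), hi)
    return [(s, lo, hi) for (s, lo), hi in windows.items()]


def align_filter_tags(
    tags: pd.DataFrame,
    assembly: dict[str, str],
    min_len: int = MIN_TAG_HIT_LEN,
    min_ident: float = MIN_TAG_IDENTITY,
    seed_k: int = TAG_SEED_K,
) -> pd.DataFrame:
    """Seed-and-extend local alignment of marker tags against an assembly.

    Hits with alignment length > ``min_len`` and identity > ``min_ident``
    (both strict, as printed) are kept; the returned table carries one row
    per surviving hit plus a per-marker status column
    (unique / duplicate / unplaced).
    """
    index = _SeedIndex(assembly, k=seed_k)
    seq_lens = [len(assembly[n]) for n in index.names]
    hit_rows = []
    for tg in tags.itertuples():
        tag = tg.tag
        codes, qpos = kmer_codes_with_positions(encode_bases(tag), seed_k)
        if codes.size == 0:
            continue
        canon = canonical_codes(codes, seed_k)
        qpos_all, tpos_all, sid_all = [], [], []
        for qi, tpos, sids in index.hits(canon):
            qpos_all.extend([qpos[qi]] * tpos.size)
            tpos_all.extend(tpos)
            sid_all.extend(sids)
        if not tpos_all:
            continue
        best_by_span: dict[tuple[int, int, int], tuple] = {}
        for s, lo, hi in _candidate_windows(len(tag), qpos_all, tpos_all, sid_all, seq_lens):
            window = assembly[index.names[s]][lo:hi]
            for orient, q in (("+", tag), ("-", revcomp(tag))):
                res = edlib.align(q, window, mode="HW", task="locations")
                if res["editDistance"] < 0 or not res["locations"]:
                    continue
                t0, t1 = res["locations"][0]
                aln_len = max(t1 - t0 + 1, len(q))
                ident = 100.0 * (aln_len - res["editDistance"]) / aln_len
                if aln_len > min_len and ident > min_ident:
                    key = (s, (lo + t0) // 50, 0)
                    cand = (tg.marker, index.names[s], lo + t0, lo + t1 + 1, aln_len, ident, orient)
                    prev = best_by_span.get(key)
                    if prev is None or ident > prev[5]:
                        best_by_span[key] = cand
        hit_rows.extend(best_by_span.values())
    hits = pd.DataFrame(
        hit_rows, columns=["marker", "target", "start", "end", "length", "identity", "strand"]
    )
    # collapse hits of the same marker overlapping on the target
    deduped = []
    for marker, sub in hits.groupby("marker"):
        sub = sub.sort_values(["target", "start"])
        kept: list = []
        for row in sub.itertuples(index=False):
            if kept and row.target == kept[-1].target and row.start < kept[-1].end:
                if row.identity > kept[-1].identity:
                    kept[-1] = row
                continue
            kept.append(row)
        deduped.extend(kept)
    hits = pd.DataFrame(deduped, columns=hits.columns) if deduped else hits

    n_hits = hits.groupby("marker").size() if not hits.empty else pd.Series(dtype=int)
    status = pd.Series("unplaced", index=tags["marker"], name="status")
    status.loc[n_hits[n_hits == 1].index] = "unique"
    status.loc[n_hits[n_hits >= 2].index] = "duplicate"
    hits = hits.merge(status.reset_index(), on="marker", how="left")
    hits.attrs["status"] = status
    return hits


# ---------------------------------------------------------------- collinearity


@dataclasses.dataclass
class CollinearityReport:
    per_group: pd.DataFrame  # linkage_group, n_markers, abs_rho, target
    mean_abs_rho: float
    n_unique: int
    n_duplicate: int
    duplicate_rate: float

    def to_json_dict(self) -> dict:
        return {
            "mean_abs_rho": self.mean_abs_rho,
            "n_unique": self.n_unique,
            "n_duplicate": self.n_duplicate,
            "duplicate_rate": self.duplicate_rate,
            "groups": self.per_group.to_dict(orient="records"),
        }


def collinearity(markers: pd.DataFrame, hits: pd.DataFrame) -> CollinearityReport:
    """Genetic-vs-physical collinearity of uniquely placed markers.

    Physical position is the hit-interval midpoint. Per linkage group the
    markers on the group's majority target sequence enter a Spearman
    correlation of cM vs midpoint; |rho| is reported (orientation is
    arbitrary) and groups with < 3 such markers are excluded from the mean.
    The duplicate rate is duplicates / placed markers. The report is
    invariant to marker input order.
    """
    status = hits.drop_duplicates("marker").set_index("marker")["status"] if not hits.empty else pd.Series(dtype=object)
    n_unique = int((status == "unique").sum())
    n_dup = int((status == "duplicate").sum())
    placed = n_unique + n_dup
    uniq_hits = hits[hits["status"] == "unique"].copy() if not hits.empty else hits
    merged = markers.merge(uniq_hits, on="marker", how="inner") if not hits.empty else pd.DataFrame()
    rows = []
    for lg in sorted(markers["linkage_group"].unique()):
        sub = merged[merged["linkage_group"] == lg] if not merged.empty else merged
        if sub is None or len(sub) == 0:
            rows.append((lg, 0, np.nan, None))
            continue
        target = sub["target"].value_counts().idxmax()
        sub = sub[sub["target"] == target]
        if len(sub) < 3:
            rows.append((lg, len(sub), np.nan, target))
            continue
        mid = (sub["start"] + sub["end"]) / 2.0
        rho = spearmanr(sub["cM"], mid).statistic
        rows.append((lg, len(sub), abs(float(rho)), target))
    per_group = pd.DataFrame(rows, columns=["linkage_group", "n_markers", "abs_rho", "target"])
    valid = per_group["abs_rho"].dropna()
    return CollinearityReport(
        per_group=per_group,
        mean_abs_rho=float(valid.mean()) if len(valid) else float("nan"),
        n_unique=n_unique,
        n_duplicate=n_dup,
        duplicate_rate=n_dup / placed if placed else 0.0,
    )
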