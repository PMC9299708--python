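"""Depth-cutoff contig classification, haplotig association and placement.

Mirrors the manual purge workflow of read-depth based deduplication: a
contig whose mapped short-read depth sits in the 1x (heterozygous) band and
that mostly aligns to a longer contig is a retained haplotig; near-zero
depth is junk; far above the 2x band is a collapsed repeat; everything else
stays primary. Haplotigs are then associated to the primary contig carrying
their longest summed alignments and placed full length: the placement
interval is the colinear chain span extended by the unaligned haplotig
prefix/suffix, so large haplotype-specific SVs at haplotig ends are not
truncated away.
"""

from __future__ import annotations

import dataclasses
import logging
import re

import pandas as pd

from . import io as dio
from .svscan import Chain

logger = logging.getLogger(__name__)

LABELS = ("JUNK", "HAPLOTIG", "PRIMARY", "REPEAT")

# the printed manual depth-cutoff sextuple of the study workflow
DEFAULT_CUTOFFS = (5, 76, 126, 151, 252, 453)


@dataclasses.dataclass(frozen=True)
class DepthCutoffs:
    """Six ascending multiplicities: junk_max, het_lo, het_peak, het_hi,
    dip_hi, repeat_max. Semantics used here: depth <= junk_max is junk,
    (junk_max, het_hi] is the haplotig candidate band, > repeat_max is
    collapsed repeat."""

    junk_max: int
    het_lo: int
    het_peak: int
    het_hi: int
    dip_hi: int
    repeat_max: int

    def __post_init__(self):
        vals = dataclasses.astuple(self)
        if any(b <= a for a, b in zip(vals, vals[1:])) or vals[0] < 0:
            raise ValueError(f"cutoffs must be strictly ascending positive: {vals}")

    @classmethod
    def from_string(cls, s: str) -> "DepthCutoffs":
        return cls(*(int(x) for x in s.split(",")))

    @classmethod
    def scaled(cls, haploid_kcov: float, template=DEFAULT_CUTOFFS) -> "DepthCutoffs":
        """Scale the canonical sextuple (template het peak 126) to a run's
        per-haplotype coverage; rounding ties are bumped to stay ascending."""
        f = haploid_kcov / template[2]
        vals = []
        for v in template:
            x = max(1, round(v * f))
            if vals and x <= vals[-1]:
                x = vals[-1] + 1
            vals.append(x)
        return cls(*vals)


def _natural_key(s: str):
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", s)]


# -------------------------------------------------------------- classification


def _aligned_fraction_to_longer(
    contig: str,
    length: int,
    lengths: dict[str, int],
    alignments: list[dio.PafRecord],
    min_identity: float,
) -> float:
    """Fraction of the contig covered by alignments (as query) to strictly
    longer contigs at >= min_identity."""
    ivals = []
    for rec in alignments:
        if rec.query != contig or rec.target == contig:
            continue
        if rec.identity < min_identity:
            continue
        if lengths.get(rec.target, 0) <= length:
            continue
        ivals.append((rec.query_start, rec.query_end))
    if not ivals:
        return 0.0
    ivals.sort()
    covered = 0
    cur_s, cur_e = ivals[0]
    for s, e in ivals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / length


def classify_contigs(
    contigs: dict[str, str] | dict[str, int],
    depths: pd.DataFrame,
    alignments: list[dio.PafRecord],
    cutoffs: DepthCutoffs,
    min_hap_align_frac: float = 0.8,
    min_identity: float = 90.0,
) -> pd.DataFrame:
    """Label every contig JUNK / HAPLOTIG / PRIMARY / REPEAT.

    ``contigs`` maps id to sequence or length; ``depths`` is a DataFrame
    with columns contig, mean_depth (from short-read mapping).
    """
    lengths = {k: (len(v) if isinstance(v, str) else int(v)) for k, v in contigs.items()}
    depth_map = dict(zip(depths["contig"], depths["mean_depth"]))
    missing = set(lengths) - set(depth_map)
    if missing:
        raise ValueError(f"no depth for contigs: {sorted(missing)[:5]} ...")
    rows = []
    for cid, length in lengths.items():
        d = depth_map[cid]
        frac = _aligned_fraction_to_longer(cid, length, lengths, alignments, min_identity)
        if d <= cutoffs.junk_max:
            label = "JUNK"
        elif d > cutoffs.repeat_max:
            label = "REPEAT"
        elif d <= cutoffs.het_hi and frac >= min_hap_align_frac:
            label = "HAPLOTIG"
        else:
            label = "PRIMARY"
        rows.append((cid, label, float(d), frac))
    return pd.DataFrame(rows, columns=["contig", "label", "mean_depth", "aligned_frac"])


# ----------------------------------------------------------------- association


def associate_haplotigs(
    haplotigs: list[str],
    alignments: list[dio.PafRecord],
) -> pd.DataFrame:
    """Associate each haplotig with the primary carrying its longest summed
    alignments; ties broken by natural-numeric smallest primary id."""
    sums: dict[str, dict[str, int]] = {h: {} for h in haplotigs}
    for rec in alignments:
        if rec.query in sums and rec.target != rec.query:
            sums[rec.query][rec.target] = sums[rec.query].get(rec.target, 0) + (
                rec.query_end - rec.query_start
            )
    rows = []
    for h in haplotigs:
        if not sums[h]:
            logger.warning("haplotig %s has no alignments; unassociated", h)
            rows.append((h, None, 0))
            continue
        best_bp = max(sums[h].values())
        tied = sorted((t for t, bp in sums[h].items() if bp == best_bp), key=_natural_key)
        if len(tied) > 1:
            logger.info("haplotig %s tie between %s; keeping %s", h, tied, tied[0])
        rows.append((h, tied[0], best_bp))
    return pd.DataFrame(rows, columns=["haplotig", "primary", "aligned_bp"])


def rename_haplotigs(association: pd.DataFrame) -> dict[str, str]:
    """FALCON-Unzip style names: haplotigs become <primary>_NNN."""
    mapping = {}
    counters: dict[str, int] = {}
    for r in association.sort_values("haplotig", key=lambda s: s.map(_natural_key)).itertuples():
        if r.primary is None:
            continue
        n = counters.get(r.primary, 0) + 1
        counters[r.primary] = n
        mapping[r.haplotig] = f"{r.primary}_{n:03d}"
    return mapping


# ------------------------------------------------------------------- placement


@dataclasses.dataclass
class Placement:
    haplotig: str
    primary: str
    start: int  # full-length primary interval (0-based half-open)
    end: int
    trunc_start: int  # alignment-only placement for comparison
    trunc_end: int
    strand: str
    haplotig_start: int  # haplotig interval used (original strand coords)
    haplotig_end: int
    full_length: bool
    clipped_left: int
    clipped_right: int


def place_full_length(chain: Chain) -> Placement:
    """Full-length placement of a haplotig on its associated primary.

    The chain's primary interval is extended by the unaligned haplotig
    prefix and suffix lengths (clipped at the primary bounds; the clip
    lengths are reported), so the placement covers the entire haplotig.
    """
    rs, re_ = chain.ref_span()
    qs, qe = chain.query_span_chainframe()
    prefix = qs
    suffix = chain.query_len - qe
    start = rs - prefix
    end = re_ + suffix
    clipped_left = max(0, -start)
    clipped_right = max(0, end - chain.ref_len)
    start = max(0, start)
    end = min(chain.ref_len, end)
    return Placement(
        haplotig=chain.query_id,
        primary=chain.ref_id,
        start=start,
        end=end,
        trunc_start=rs,
        trunc_end=re_,
        strand=chain.strand,
        haplotig_start=0,
        haplotig_end=chain.query_len,
        full_length=True,
        clipped_left=clipped_left,
        clipped_right=clipped_right,
    )


def placements_to_bed(placements: list[Placement]) -> list[dio.BedRecord]:
    return [
        dio.BedRecord(p.primary, p.start, p.end, p.haplotig, ".", p.strand) for p in placements
    ]
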