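"""Synthetic diploid genome with full ground truth.

Generates a heterozygous diploid (hapA + hapB) whose truth tables make every
downstream stage testable without external data: planted repeat families,
SNPs and small indels, six classes of structural variant, gene models with
allele-specific-expression (ASE) truth categories, short reads, a fragmented
"assembly" with haplotigs, simulated mapping depths, allelic count tables
and a linkage-map marker set.

Construction is an explicit edit script: hapB is obtained by applying the
truth variants to hapA left to right, so the reconstruction invariant
(truth tables + hapA == hapB, byte identical) holds by bookkeeping that the
tests verify independently.

Repeat handling: copies within a family are exact, and the small variants
that distinguish hapB from hapA inside a family are applied identically to
every copy (family-level divergence). The per-bp polymorphism rate is still
uniform genome-wide, but single-copy heterozygous k-mers then arise only
from unique sequence, which is what a two-peak k-mer profile can resolve.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio

logger = logging.getLogger(__name__)

SV_CATEGORIES = (
    "insertion",
    "deletion",
    "repeat_expansion",
    "repeat_contraction",
    "tandem_expansion",
    "tandem_contraction",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = dict(zip(b"ACGT", b"TGCA"))
_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in _COMP.items():
    _COMP_TABLE[_a] = _b

# RNG stream tags so each stage has an independent, reproducible stream
_STREAM_GENOME, _STREAM_READS, _STREAM_FRAG, _STREAM_COUNTS, _STREAM_MAP = range(5)


class PlacementError(RuntimeError):
    """Requested features cannot be placed without overlap."""


# ------------------------------------------------------------------- config


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic diploid.

    Rates are fractions per bp; SV sizes in bp. ``het_snp_rate`` and
    ``small_indel_rate`` together are the per-bp polymorphism rate that a
    k-mer profile reports as heterozygosity.
    """

    haploid_length: int = 1_000_000
    het_snp_rate: float = 0.0141 / 1.1
    small_indel_rate: float = 0.0141 / 11.0  # default: 10% of the SNP rate
    small_indel_len_range: tuple[int, int] = (1, 9)  # small indels are <50 bp
    repeat_fraction: float = 0.61
    repeat_unit_range: tuple[int, int] = (200, 5000)
    repeat_copy_range: tuple[int, int] = (3, 12)
    sv_counts: dict = dataclasses.field(default_factory=dict)
    sv_size_range: tuple[int, int] = (50, 10_000)
    sv_size_log_uniform: bool = True
    n_genes: int = 0
    gene_len_range: tuple[int, int] = (500, 3000)
    n_tissues: int = 3
    ase_complete_fraction: float = 0.08
    ase_partial_fraction: float = 0.12
    ase_partial_p_range: tuple[float, float] = (0.6, 0.95)
    ase_sv_link_distance: int = 5000
    ase_sv_linked_fraction: float = 0.0  # fraction of complete-ASE genes with a nearby INDEL
    ase_mean_depth: float = 100.0
    ase_depth_dispersion: float = 10.0  # negative-binomial size parameter
    ase_min_gene_sv_gap: int = 200
    read_length: int = 150
    coverage_per_haplotype: float = 40.0
    read_error_rate: float = 0.0
    seed: int = 1

    def validate(self) -> None:
        if self.haploid_length <= 0:
            raise ValueError(f"haploid_length must be positive, got {self.haploid_length}")
        for name in ("het_snp_rate", "small_indel_rate", "repeat_fraction",
                     "read_error_rate", "ase_complete_fraction",
                     "ase_partial_fraction", "ase_sv_linked_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.sv_size_range
        if not (50 <= lo <= hi <= 10_000):
            raise ValueError(f"sv_size_range {self.sv_size_range} outside [50, 10000]")
        if self.sv_counts and self.haploid_length < 10 * hi:
            raise ValueError("haploid_length must be >= 10 x max SV size")
        if self.ase_complete_fraction + self.ase_partial_fraction > 1.0:
            raise ValueError("ASE category fractions exceed 1")
        unknown = set(self.sv_counts) - set(SV_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown SV categories: {sorted(unknown)}")
        if not (1 <= self.small_indel_len_range[0] <= self.small_indel_len_range[1] <= 49):
            raise ValueError("small indel lengths must be within 1-49 bp")

    def manifest_entries(self) -> dict:
        d = dataclasses.asdict(self)
        d["sv_counts"] = ",".join(f"{k}:{v}" for k, v in sorted(self.sv_counts.items()))
        return {f"config.{k}": v for k, v in d.items()}


def tme7_preset(
    haploid_length: int = 1_000_000, seed: int = 1, n_genes: int = 0, **overrides
) -> SimConfig:
    """The TME7-like study preset: 1.41% per-bp polymorphism (SNP:indel
    10:1), 61% repeat content, and SV class counts in the proportions of the
    haplotype-specific SV summary (~7.7 SVs per Mb, size log-uniform in
    50-10,000 bp), ASE prevalence ~20% per tissue of which 8 points complete.
    """
    table3 = {
        "insertion": 1047,
        "deletion": 902,
        "repeat_expansion": 1587,
        "repeat_contraction": 1804,
        "tandem_expansion": 58,
        "tandem_contraction": 10,
    }
    total = 5408
    per_mb = total / 700.0  # genome-scale density: 5408 SVs on ~700 Mb
    n_sv = per_mb * haploid_length / 1e6
    sv_counts = {
        cat: max(1, round(n_sv * cnt / total)) if n_sv >= 1 else 0
        for cat, cnt in table3.items()
    }
    cfg = SimConfig(
        haploid_length=haploid_length,
        sv_counts=sv_counts,
        n_genes=n_genes,
        ase_sv_linked_fraction=1.0 if n_genes else 0.0,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    # linked INDELs near complete-ASE genes are drawn from sv_counts, so the
    # preset must request at least that many insertion/deletion SVs
    need = round(cfg.ase_sv_linked_fraction * round(cfg.ase_complete_fraction * cfg.n_genes))
    have = cfg.sv_counts.get("insertion", 0) + cfg.sv_counts.get("deletion", 0)
    if need > have:
        deficit = need - have
        cfg.sv_counts["insertion"] = cfg.sv_counts.get("insertion", 0) + (deficit + 1) // 2
        cfg.sv_counts["deletion"] = cfg.sv_counts.get("deletion", 0) + deficit // 2
    cfg.validate()
    return cfg


def divergence_preset(seed: int = 1, length: int = 100_000, target_divergence: float = 2.09) -> SimConfig:
    """Preset for haplotig/primary divergence recovery.

    Alignment divergence counts mismatches plus indel bases over aligned
    columns, so the planted SNP rate s is solved from
    target = s (1 + 0.1 * mean_len) / (1 + 0.05 * s * mean_len)
    with indel events at 10% of SNP events and lengths uniform in 1..9.
    """
    lmin, lmax = 1, 9
    mean_len = (lmin + lmax) / 2.0
    t = target_divergence / 100.0
    s = t / (1 + 0.1 * mean_len - 0.05 * mean_len * t)
    return SimConfig(
        haploid_length=length,
        het_snp_rate=s,
        small_indel_rate=0.1 * s,
        small_indel_len_range=(lmin, lmax),
        repeat_fraction=0.0,
        sv_counts={},
        seed=seed,
    )


# ---------------------------------------------------------------- containers


@dataclasses.dataclass
class DiploidGenome:
    hapA: dict[str, str]
    hapB: dict[str, str]
    truth_snps: pd.DataFrame  # chrom, pos, ref, alt
    truth_small_indels: pd.DataFrame  # chrom, pos, ref, alt
    truth_svs: pd.DataFrame  # chrom, start, end, category, size, alt_seq, tract_start, tract_end
    truth_repeats: pd.DataFrame  # chrom, start, end, family
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, truth_category
    config: SimConfig

    @property
    def chrom(self) -> str:
        return next(iter(self.hapA))

    def edits(self) -> pd.DataFrame:
        """All hapA->hapB edits as (chrom, pos, ref_len, alt), sorted."""
        rows = []
        for r in self.truth_snps.itertuples():
            rows.append((r.chrom, r.pos, 1, r.alt))
        for r in self.truth_small_indels.itertuples():
            rows.append((r.chrom, r.pos, len(r.ref), r.alt))
        for r in self.truth_svs.itertuples():
            rows.append((r.chrom, r.start, r.end - r.start, r.alt_seq))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref_len", "alt"])
        return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    def reconstruct_hapB(self) -> dict[str, str]:
        """Apply the truth tables to hapA (the reconstruction invariant)."""
        edits = self.edits()
        out = {}
        for name, seq in self.hapA.items():
            sub = edits[edits["chrom"] == name]
            out[name.replace("hapA", "hapB")] = _apply_edits(
                seq, list(zip(sub["pos"], sub["ref_len"], sub["alt"]))
            )
        return out

    def hapA_to_hapB_coord(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Map hapA coordinates to hapB through the edit script."""
        edits = self.edits()
        sub = edits[edits["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        delta = (sub["alt"].str.len() - sub["ref_len"]).to_numpy()
        ends = pos + sub["ref_len"].to_numpy()
        cum = np.concatenate(([0], np.cumsum(delta)))
        idx = np.searchsorted(ends, positions, side="right")
        return positions + cum[idx]


@dataclasses.dataclass
class ReadSet:
    """Simulated short reads; parallel arrays plus constant Q30 qualities."""

    ids: list[str]
    sequences: list[str]
    haplotype: list[str]
    chrom: list[str]
    start: np.ndarray
    strand: list[str]

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, i: int):
        return Read(
            self.ids[i], self.sequences[i], self.haplotype[i],
            self.chrom[i], int(self.start[i]), self.strand[i],
        )

    def total_bases(self) -> int:
        return sum(len(s) for s in self.sequences)

    def to_fastq(self, path) -> None:
        dio.write_fastq(
            path, ((i, s, "I" * len(s)) for i, s in zip(self.ids, self.sequences))
        )


@dataclasses.dataclass
class Read:
    id: str
    sequence: str
    haplotype: str
    chrom: str
    start: int
    strand: str


@dataclasses.dataclass
class FragmentedAssembly:
    primaries: dict[str, str]
    haplotigs: dict[str, str]
    junk: dict[str, str]
    truth_map: pd.DataFrame  # contig, role, hap, chrom, src_start, src_end, a_start, a_end
    withheld: pd.DataFrame  # chrom, a_start, a_end, b_start, b_end

    def all_contigs(self) -> dict[str, str]:
        return {**self.primaries, **self.haplotigs, **self.junk}


# ------------------------------------------------------------ sequence utils


def _random_seq_array(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return _random_seq_array(rng, n).tobytes().decode()


def revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMP_TABLE[arr][::-1].tobytes().decode()


def _apply_edits(seq: str, edits: list[tuple[int, int, str]]) -> str:
    """Apply non-overlapping (pos, ref_len, alt) edits left to right."""
    parts = []
    cursor = 0
    for pos, ref_len, alt in edits:
        if pos < cursor:
            raise ValueError(f"overlapping edits at {pos} (cursor {cursor})")
        parts.append(seq[cursor:pos])
        parts.append(alt)
        cursor = pos + ref_len
    parts.append(seq[cursor:])
    return "".join(parts)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


# ------------------------------------------------------------ genome builder


def _plan_repeats(rng, cfg) -> tuple[list[tuple[str, str]], int]:
    """Repeat family copies as (family, unit_seq) pairs to disperse."""
    target = int(cfg.repeat_fraction * cfg.haploid_length)
    copies: list[tuple[str, str]] = []
    placed = 0
    fam = 0
    while placed < target:
        umin, umax = cfg.repeat_unit_range
        unit_len = int(rng.integers(umin, umax + 1))
        n_copies = int(rng.integers(cfg.repeat_copy_range[0], cfg.repeat_copy_range[1] + 1))
        if placed + unit_len * n_copies > target:  # shrink final family to the budget
            unit_len = (target - placed) // n_copies
            if unit_len < 50:
                break
        unit = random_sequence(rng, unit_len)
        name = f"fam{fam:03d}"
        copies.extend((name, unit) for _ in range(n_copies))
        placed += unit_len * n_copies
        fam += 1
    return copies, placed


def _assemble_hapA(rng, cfg) -> tuple[np.ndarray, pd.DataFrame, dict[str, str]]:
    """Backbone of unique sequence with dispersed repeat copies."""
    copies, repeat_bp = _plan_repeats(rng, cfg)
    backbone_len = cfg.haploid_length - repeat_bp
    if backbone_len < 0:
        raise PlacementError("repeat_fraction leaves no unique backbone")
    order = rng.permutation(len(copies))
    # repeat copies are clustered (TE-dense blocks), leaving contiguous
    # unique stretches between clusters, as in real plant chromosome arms
    n_clusters = max(1, len(copies) // 8)
    centers = rng.integers(0, backbone_len + 1, size=n_clusters)
    assign = rng.integers(0, n_clusters, size=len(copies))
    cuts = np.sort(
        np.clip(centers[assign] + rng.normal(0, 3000, len(copies)).astype(np.int64), 0, backbone_len)
    )
    backbone = _random_seq_array(rng, backbone_len)
    pieces = []
    intervals = []
    units: dict[str, str] = {}
    cursor = 0
    out_pos = 0
    for cut, oi in zip(cuts, order):
        fam, unit = copies[oi]
        units.setdefault(fam, unit)
        pieces.append(backbone[cursor:cut])
        out_pos += cut - cursor
        ua = np.frombuffer(unit.encode(), dtype=np.uint8)
        pieces.append(ua)
        intervals.append((out_pos, out_pos + len(unit), fam))
        out_pos += len(unit)
        cursor = cut
    pieces.append(backbone[cursor:])
    hapA = np.concatenate(pieces) if pieces else backbone
    rep = pd.DataFrame(intervals, columns=["start", "end", "family"])
    return hapA, rep, units


def _find_free_span(rng, blocked, length, lo=0, hi=None, tries=200):
    hi = min(blocked.size if hi is None else hi, blocked.size) - length
    lo = max(lo, 0)
    if hi <= lo:
        return None
    for _ in range(tries):
        pos = int(rng.integers(lo, hi))
        if not blocked[pos : pos + length].any():
            return pos
    # random probing failed; enumerate free runs and sample a feasible start
    window = blocked[lo : hi + length]
    d = np.diff(np.concatenate(([1], window.view(np.int8), [1])))
    starts = np.where(d == -1)[0]
    slack = np.where(d == 1)[0] - starts - length
    slack = np.minimum(slack, hi - lo - 1 - starts)
    ok = slack >= 0
    if not ok.any():
        return None
    starts, slack = starts[ok], slack[ok]
    weights = (slack + 1).astype(float)
    run = int(rng.choice(starts.size, p=weights / weights.sum()))
    return lo + int(starts[run]) + int(rng.integers(0, slack[run] + 1))


def generate_diploid(cfg: SimConfig) -> DiploidGenome:
    """Build hapA, derive hapB by planting variants, emit full truth tables.

    Placement order: repeat families, genes, SVs (with exclusion buffers of
    2 x max SV size between SVs; INDEL-class SVs linked to complete-ASE
    genes are placed first, within ``ase_sv_link_distance`` of the gene),
    then SNPs and small indels everywhere outside SV footprints. Raises
    :class:`PlacementError` when a feature cannot be placed.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, _STREAM_GENOME])
    L = cfg.haploid_length
    chromA = "hapA_1"

    hapA_arr, repeats, fam_units = _assemble_hapA(rng, cfg)
    repeats.insert(0, "chrom", chromA)
    blocked = np.zeros(L, dtype=bool)  # blocked for feature placement
    for r in repeats.itertuples():
        blocked[r.start : r.end] = True

    # ---- genes ----
    gene_rows = []
    n_complete = round(cfg.ase_complete_fraction * cfg.n_genes)
    n_partial = round(cfg.ase_partial_fraction * cfg.n_genes)
    categories = (
        ["complete"] * n_complete
        + ["partial"] * n_partial
        + ["none"] * (cfg.n_genes - n_complete - n_partial)
    )
    rng.shuffle(categories)
    for gi in range(cfg.n_genes):
        glen = int(rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1))
        pos = _find_free_span(rng, blocked, glen + 2 * cfg.ase_min_gene_sv_gap)
        if pos is None:
            raise PlacementError(f"cannot place gene {gi} of {cfg.n_genes}")
        start = pos + cfg.ase_min_gene_sv_gap
        blocked[pos : pos + glen + 2 * cfg.ase_min_gene_sv_gap] = True
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"gene{gi:05d}", chromA, start, start + glen, strand, categories[gi]))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "truth_category"]
    )

    # ---- SVs ----
    max_sv = cfg.sv_size_range[1]
    buffer = 2 * max_sv
    sv_rows: list[dict] = []
    edits: list[tuple[int, int, str]] = []
    hapA_mut = bytearray(hapA_arr.tobytes())
    sv_blocked = blocked.copy()
    # footprints plus a fixed clean margin only: the relaxed mask used when a
    # linked INDEL's window is covered by another SV's exclusion buffer
    sv_foot_blocked = blocked.copy()
    _FOOT_MARGIN = 300

    def draw_size(rng) -> int:
        lo, hi = cfg.sv_size_range
        if cfg.sv_size_log_uniform:
            return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        return int(rng.integers(lo, hi + 1))

    def sv_footprint(cat: str, size: int) -> tuple[int, int, int]:
        """(hapA footprint length, n copies before, unit length) per class."""
        if cat == "insertion":
            return 0, 0, 0
        if cat == "deletion":
            return size, 0, 0
        if cat == "tandem_expansion":  # 2 -> 4 copies of unit u = size/2
            u = size // 2
            return 2 * u, 2, u
        if cat == "tandem_contraction":  # 4 -> 2 copies
            u = size // 2
            return 4 * u, 4, u
        if cat == "repeat_expansion":  # 2 -> 5 copies, u = size/3
            u = size // 3
            return 2 * u, 2, u
        if cat == "repeat_contraction":  # 5 -> 2 copies
            u = size // 3
            return 5 * u, 5, u
        raise ValueError(cat)

    def plant_sv(cat: str, pos_hint: tuple[int, int] | None, size_draws: int = 20) -> bool:
        pos = None
        for _ in range(size_draws):  # large footprints re-draw their size
            size = draw_size(rng)
            # unit-based classes need unit >= ~35 bp so sizes stay faithful
            if cat in ("repeat_expansion", "repeat_contraction"):
                size = max(size, 105)
                size = (size // 3) * 3
            elif cat in ("tandem_expansion", "tandem_contraction"):
                size = max(size, 70)
                size = (size // 2) * 2
            foot, n_before, u = sv_footprint(cat, size)
            span = max(foot, 1)
            if pos_hint is None:
                pos = _find_free_span(rng, sv_blocked, span, tries=400)
            else:
                lo, hi = pos_hint
                pos = _find_free_span(rng, sv_blocked, span, lo=lo, hi=hi, tries=400)
                if pos is None:
                    # window may be covered by a neighbouring SV's exclusion
                    # buffer; accept anywhere clear of actual footprints
                    pos = _find_free_span(rng, sv_foot_blocked, span, lo=lo, hi=hi, tries=400)
            if pos is not None:
                break
        if pos is None:
            return False
        row = dict(chrom=chromA, category=cat, size=size)
        if cat == "insertion":
            alt = random_sequence(rng, size)
            row.update(start=pos, end=pos, alt_seq=alt, tract_start=pos, tract_end=pos)
        elif cat == "deletion":
            row.update(
                start=pos, end=pos + size, alt_seq="", tract_start=pos, tract_end=pos + size
            )
        else:
            unit = random_sequence(rng, u)
            tract = unit * n_before
            hapA_mut[pos : pos + len(tract)] = tract.encode()
            if cat.endswith("expansion"):
                extra = size // u
                row.update(
                    start=pos + len(tract), end=pos + len(tract),
                    alt_seq=unit * extra, tract_start=pos, tract_end=pos + len(tract),
                )
            else:
                n_after = n_before - size // u
                cut = pos + n_after * u
                row.update(
                    start=cut, end=cut + size, alt_seq="",
                    tract_start=pos, tract_end=pos + len(tract),
                )
        # the exclusion buffer (2 x the SV's size) keeps SVs apart but may
        # cover repeats or genes; only the footprint must be feature-free
        buf = 2 * max(size, span)
        lo_b = max(0, pos - buf)
        sv_blocked[lo_b : pos + span + buf] = True
        sv_foot_blocked[max(0, pos - _FOOT_MARGIN) : pos + span + _FOOT_MARGIN] = True
        blocked[max(0, pos - 1) : pos + span + 1] = True  # exclude small variants
        sv_rows.append(row)
        return True

    # linked INDELs near complete-ASE genes come out of the requested counts
    counts = dict(cfg.sv_counts)
    complete_genes = genes[genes["truth_category"] == "complete"]
    n_linked = round(cfg.ase_sv_linked_fraction * len(complete_genes))
    linked_genes = complete_genes.head(n_linked)
    for g in linked_genes.itertuples():
        cat = "deletion" if counts.get("deletion", 0) >= counts.get("insertion", 0) else "insertion"
        if counts.get(cat, 0) == 0:
            cat = "insertion" if counts.get("insertion", 0) else "deletion"
        if counts.get(cat, 0) == 0:
            raise PlacementError(
                "ase_sv_linked_fraction requires more insertion/deletion SVs than sv_counts provides"
            )
        side_first = rng.random() < 0.5
        # _find_free_span treats hi as the exclusive end of the footprint
        windows = [
            (g.end + cfg.ase_min_gene_sv_gap, g.end + cfg.ase_sv_link_distance),
            (g.start - cfg.ase_sv_link_distance, g.start - cfg.ase_min_gene_sv_gap),
        ]
        if not side_first:
            windows.reverse()
        ok = plant_sv(cat, windows[0]) or plant_sv(cat, windows[1])
        if not ok:
            raise PlacementError(f"cannot place linked INDEL near {g.gene_id}")
        counts[cat] -= 1

    for cat in SV_CATEGORIES:  # deterministic order by category
        for _ in range(counts.get(cat, 0)):
            if not plant_sv(cat, None):
                raise PlacementError(f"cannot place SV of class {cat}")

    hapA_seq = hapA_mut.decode()
    truth_svs = pd.DataFrame(
        sv_rows,
        columns=["chrom", "start", "end", "category", "size", "alt_seq", "tract_start", "tract_end"],
    )
    for r in truth_svs.itertuples():  # SV edits
        edits.append((r.start, r.end - r.start, r.alt_seq))

    # ---- small variants: unique regions per-bp, repeat families per-unit ----
    snp_rows: list[tuple] = []
    indel_rows: list[tuple] = []
    ilo, ihi = cfg.small_indel_len_range

    # small variants are excluded from SV footprints plus a 100 bp clean
    # flank, so anchor extension can reach each SV's breakpoints
    blocked_small = np.zeros(L, dtype=bool)
    sv_flank = 100
    for r in truth_svs.itertuples():
        lo = max(0, r.tract_start - sv_flank)
        blocked_small[lo : max(r.tract_end, r.end) + sv_flank] = True

    in_repeat = np.zeros(L, dtype=bool)
    for r in repeats.itertuples():
        in_repeat[r.start : r.end] = True

    # unique regions
    uniq_local_blocked = blocked_small | in_repeat
    u = rng.random(L)
    snp_pos = np.nonzero((u < cfg.het_snp_rate) & ~uniq_local_blocked)[0]
    taken = np.zeros(L, dtype=bool)
    taken[snp_pos] = True
    v = rng.random(L)
    cand = np.nonzero((v < cfg.small_indel_rate) & (u >= cfg.het_snp_rate) & ~uniq_local_blocked)[0]
    for pos in snp_pos:
        ref = hapA_seq[pos]
        snp_rows.append((chromA, int(pos), ref, _other_base(rng, ref)))
    for pos in cand:
        length = int(rng.integers(ilo, ihi + 1))
        is_del = rng.random() < 0.5
        span = length if is_del else 1
        if pos + span > L or taken[pos : pos + span].any() or uniq_local_blocked[pos : pos + span].any():
            continue
        taken[pos : pos + span] = True
        if is_del:
            indel_rows.append((chromA, int(pos), hapA_seq[pos : pos + length], ""))
        else:
            indel_rows.append((chromA, int(pos), "", random_sequence(rng, length)))

    # repeat families: identical consensus edits in every copy
    for fam, unit in fam_units.items():
        ulen = len(unit)
        cu = rng.random(ulen)
        fam_snps = np.nonzero(cu < cfg.het_snp_rate)[0]
        ftaken = np.zeros(ulen, dtype=bool)
        ftaken[fam_snps] = True
        cv = rng.random(ulen)
        fam_ind = []
        for off in np.nonzero((cv < cfg.small_indel_rate) & (cu >= cfg.het_snp_rate))[0]:
            length = int(rng.integers(ilo, ihi + 1))
            is_del = rng.random() < 0.5
            span = length if is_del else 1
            if off + span > ulen or ftaken[off : off + span].any():
                continue
            ftaken[off : off + span] = True
            fam_ind.append((int(off), length, is_del, random_sequence(rng, length)))
        alts = {int(off): _other_base(rng, unit[off]) for off in fam_snps}
        fam_copies = repeats[repeats["family"] == fam]
        for c in fam_copies.itertuples():
            for off, alt in alts.items():
                snp_rows.append((chromA, c.start + off, unit[off], alt))
            for off, length, is_del, ins_seq in fam_ind:
                if is_del:
                    indel_rows.append((chromA, c.start + off, unit[off : off + length], ""))
                else:
                    indel_rows.append((chromA, c.start + off, "", ins_seq))

    truth_snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt"]).sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
    truth_small_indels = pd.DataFrame(
        indel_rows, columns=["chrom", "pos", "ref", "alt"]
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    truth_svs = truth_svs.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    genome = DiploidGenome(
        hapA={chromA: hapA_seq},
        hapB={},
        truth_snps=truth_snps,
        truth_small_indels=truth_small_indels,
        truth_svs=truth_svs,
        truth_repeats=repeats,
        genes=genes,
        config=cfg,
    )
    genome.hapB = genome.reconstruct_hapB()
    return genome


# -------------------------------------------------------------------- reads


def simulate_reads(genome: DiploidGenome, cfg: SimConfig | None = None) -> ReadSet:
    """Uniform random reads from both haplotypes and strands.

    Per-base substitution errors at ``read_error_rate``; reads starting
    within ``read_length`` of the sequence end are clipped (warning logged).
    """
    cfg = cfg or genome.config
    if cfg.coverage_per_haplotype <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng([cfg.seed, _STREAM_READS])
    rl = cfg.read_length
    ids, seqs, haps, chroms, strands = [], [], [], [], []
    starts_all = []
    clipped = 0
    for hap_label, seq_dict in (("A", genome.hapA), ("B", genome.hapB)):
        for name, seq in seq_dict.items():
            n_reads = int(round(cfg.coverage_per_haplotype * len(seq) / rl))
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            starts = rng.integers(0, len(seq), size=n_reads)
            rev = rng.random(n_reads) < 0.5
            for idx in range(0, n_reads, 100_000):
                block = slice(idx, min(idx + 100_000, n_reads))
                bs = starts[block]
                brev = rev[block]
                for j, (st, rv) in enumerate(zip(bs, brev)):
                    end = min(st + rl, len(seq))
                    sub = arr[st:end]
                    if rv:
                        sub = _COMP_TABLE[sub][::-1]
                    else:
                        sub = sub.copy()
                    if cfg.read_error_rate > 0:
                        errs = np.nonzero(rng.random(sub.size) < cfg.read_error_rate)[0]
                        for e in errs:
                            sub[e] = ord(_other_base(rng, chr(sub[e])))
                    if end - st < rl:
                        clipped += 1
                    rid = f"read_{hap_label}_{name}_{idx + j}"
                    ids.append(rid)
                    seqs.append(sub.tobytes().decode())
                    haps.append(hap_label)
                    chroms.append(name)
                    strands.append("-" if rv else "+")
                    starts_all.append(st)
    if clipped:
        logger.warning("%d reads clipped at sequence ends", clipped)
    return ReadSet(ids, seqs, haps, chroms, np.asarray(starts_all), strands)


# ------------------------------------------------------------- fragmentation


def _poisson_fragments(rng, length: int, n50_target: int) -> list[tuple[int, int]]:
    """Cut [0, length) at Poisson breakpoints; exponential fragments have
    N50 ~ 1.678 x mean, so the mean spacing is n50_target / 1.678."""
    if n50_target >= length:
        return [(0, length)]
    mean = max(n50_target / 1.678, 1.0)
    cuts = []
    pos = 0.0
    while True:
        pos += rng.exponential(mean)
        if pos >= length - 1:
            break
        cuts.append(int(pos))
    bounds = [0] + sorted(set(cuts)) + [length]
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def fragment_into_contigs(
    genome: DiploidGenome,
    n50_target: int,
    drop_het_fraction: float = 0.0,
    seed: int | None = None,
    haplotig_n50: int | None = None,
    het_collapse_gap: int = 2000,
    het_margin: int = 100,
    n_junk: int = 0,
) -> FragmentedAssembly:
    """Fragment hapA into primary contigs and emit hapB heterozygous
    segments as haplotigs, withholding a fraction of them.

    Heterozygous segments are maximal runs of truth variants separated by
    homozygous gaps >= ``het_collapse_gap``, extended by ``het_margin``.
    Homozygous regions appear once (in the primary contigs only).
    """
    if n50_target > genome.config.haploid_length:
        raise ValueError("n50_target exceeds haploid length")
    seed = genome.config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_FRAG])
    haplotig_n50 = haplotig_n50 or max(n50_target // 4, 1000)
    rows = []
    primaries: dict[str, str] = {}
    haplotigs: dict[str, str] = {}
    junk: dict[str, str] = {}
    withheld_rows = []

    for name, seqA in genome.hapA.items():
        for ci, (a, b) in enumerate(_poisson_fragments(rng, len(seqA), n50_target)):
            cid = f"p_{name}_{ci:04d}"
            primaries[cid] = seqA[a:b]
            rows.append((cid, "primary", "A", name, a, b, a, b))

        # heterozygous segments on hapA coordinates
        edits = genome.edits()
        sub = edits[edits["chrom"] == name]
        vpos = sub["pos"].to_numpy()
        vend = vpos + np.maximum(sub["ref_len"].to_numpy(), 1)
        if vpos.size == 0:
            continue
        seg_bounds = []
        seg_start, seg_end = int(vpos[0]), int(vend[0])
        for p, e in zip(vpos[1:], vend[1:]):
            if p - seg_end >= het_collapse_gap:
                seg_bounds.append((seg_start, seg_end))
                seg_start = int(p)
            seg_end = max(seg_end, int(e))
        seg_bounds.append((seg_start, seg_end))

        nameB = name.replace("hapA", "hapB")
        seqB = genome.hapB[nameB]
        hi = 0
        for a0, e0 in seg_bounds:
            a = max(0, a0 - het_margin)
            e = min(len(seqA), e0 + het_margin)
            b_lo, b_hi = genome.hapA_to_hapB_coord(name, np.array([a, e]))
            b_lo, b_hi = int(b_lo), int(min(b_hi, len(seqB)))
            if rng.random() < drop_het_fraction:
                withheld_rows.append((name, a, e, b_lo, b_hi))
                continue
            for fa, fb in _poisson_fragments(rng, b_hi - b_lo, haplotig_n50):
                cid = f"h_{nameB}_{hi:04d}"
                hi += 1
                haplotigs[cid] = seqB[b_lo + fa : b_lo + fb]
                # a-coords approximate for haplotig fragments (offsets within segment)
                rows.append((cid, "haplotig", "B", nameB, b_lo + fa, b_lo + fb, a + fa, min(a + fb, e)))

    for ji in range(n_junk):
        cid = f"junk_{ji:03d}"
        junk[cid] = random_sequence(rng, int(rng.integers(1000, 10_000)))
        rows.append((cid, "junk", ".", ".", -1, -1, -1, -1))

    truth_map = pd.DataFrame(
        rows, columns=["contig", "role", "hap", "chrom", "src_start", "src_end", "a_start", "a_end"]
    )
    withheld = pd.DataFrame(
        withheld_rows, columns=["chrom", "a_start", "a_end", "b_start", "b_end"]
    )
    return FragmentedAssembly(primaries, haplotigs, junk, truth_map, withheld)


def simulate_depths(frag: FragmentedAssembly, genome: DiploidGenome, cfg: SimConfig | None = None) -> pd.DataFrame:
    """Simulated short-read mapping depth per contig.

    Best-placement mapping sends each haplotype's reads to its own copy of
    a heterozygous locus, so haplotigs and the heterozygous parts of primary
    contigs sit near 1x haplotype coverage c, collapsed (homozygous or
    haplotig-withheld) regions near 2c, and junk near 0.
    """
    cfg = cfg or genome.config
    rng = np.random.default_rng([cfg.seed, _STREAM_COUNTS])
    c = cfg.coverage_per_haplotype

    het_mask = {}
    for name, seqA in genome.hapA.items():
        mask = np.zeros(len(seqA), dtype=bool)
        edits = genome.edits()
        sub = edits[edits["chrom"] == name]
        for r in sub.itertuples():
            lo = max(0, r.pos - 100)
            mask[lo : min(len(seqA), r.pos + max(r.ref_len, 1) + 100)] = True
        # withheld segments fall back to 2c on the primary
        wh = frag.withheld[frag.withheld["chrom"] == name]
        for r in wh.itertuples():
            mask[r.a_start : r.a_end] = False
        het_mask[name] = mask

    rows = []
    for r in frag.truth_map.itertuples():
        if r.role == "junk":
            mean = 0.1
        elif r.role == "haplotig":
            mean = c
        else:
            mask = het_mask[r.chrom][r.src_start : r.src_end]
            frac_het = mask.mean() if mask.size else 0.0
            mean = c * frac_het + 2 * c * (1 - frac_het)
        length = max(r.src_end - r.src_start, 1) if r.role != "junk" else len(frag.junk[r.contig])
        depth = rng.poisson(mean * length) / length
        rows.append((r.contig, float(depth)))
    return pd.DataFrame(rows, columns=["contig", "mean_depth"])


# ------------------------------------------------------------ allelic counts


def simulate_allelic_counts(genome: DiploidGenome, cfg: SimConfig | None = None) -> pd.DataFrame:
    """Per-gene, per-tissue allelic read counts from the truth categories.

    Totals are negative-binomial around a gene-specific mean; the allelic
    split is Binomial(total, p) with p = 0.5 ("none"), p in
    ``ase_partial_p_range`` ("partial", random direction, constant per
    gene) and p in {0, 1} ("complete").
    """
    cfg = cfg or genome.config
    if cfg.n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    rng = np.random.default_rng([cfg.seed, _STREAM_COUNTS, 1])
    rows = []
    theta = cfg.ase_depth_dispersion
    for g in genome.genes.itertuples():
        mu = float(np.exp(rng.normal(np.log(cfg.ase_mean_depth), 0.5)))
        if g.truth_category == "none":
            p_alt = 0.5
        elif g.truth_category == "partial":
            p_alt = float(rng.uniform(*cfg.ase_partial_p_range))
            if rng.random() < 0.5:
                p_alt = 1.0 - p_alt
        else:
            p_alt = 1.0 if rng.random() < 0.5 else 0.0
        for t in range(cfg.n_tissues):
            total = int(rng.negative_binomial(theta, theta / (theta + mu)))
            alt = int(rng.binomial(total, p_alt))
            rows.append((g.gene_id, f"tissue{t + 1}", total - alt, alt, g.truth_category))
    return pd.DataFrame(rows, columns=["gene", "tissue", "refCount", "altCount", "truth_category"])


# -------------------------------------------------------------- linkage map


def simulate_linkage_map(
    genome: DiploidGenome,
    n_markers: int = 200,
    n_groups: int = 4,
    cm_per_mb: float = 3.4,
    seed: int | None = None,
) -> pd.DataFrame:
    """SNP-marker map over hapA: the chromosome is split into ``n_groups``
    blocks standing in for linkage groups; genetic position is proportional
    to the physical offset within the block. Markers avoid repeats so their
    flanking tags align uniquely."""
    seed = genome.config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_MAP])
    name = genome.chrom
    L = len(genome.hapA[name])
    in_repeat = np.zeros(L, dtype=bool)
    for r in genome.truth_repeats.itertuples():
        lo = max(0, r.start - 120)
        in_repeat[lo : min(L, r.end + 120)] = True
    candidates = np.nonzero(~in_repeat)[0]
    candidates = candidates[(candidates > 150) & (candidates < L - 150)]
    pos = np.sort(rng.choice(candidates, size=min(n_markers, candidates.size), replace=False))
    block = L // n_groups
    rows = []
    for i, p in enumerate(pos):
        lg = min(int(p) // block, n_groups - 1)
        cm = (int(p) - lg * block) * cm_per_mb / 1e6 * 100  # cM within block
        rows.append((f"M{i:05d}", f"LG{lg + 1}", round(cm, 4), name, int(p) + 1))
    return pd.DataFrame(rows, columns=["marker", "linkage_group", "cM", "source_seq", "source_pos"])


# ------------------------------------------------------------------ outputs


def write_genome_outputs(genome: DiploidGenome, outdir) -> None:
    """FASTA, truth VCF-lite / BED / GFF3 and the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_fasta(out / "hapA.fasta", genome.hapA)
    dio.write_fasta(out / "hapB.fasta", genome.hapB)

    recs = []
    for r in genome.truth_snps.itertuples():
        recs.append(dio.VcfLiteRecord(r.chrom, r.pos, "snp", r.ref, r.alt, {"HAP": "B"}))
    for r in genome.truth_small_indels.itertuples():
        ref = r.ref if r.ref else "-"
        alt = r.alt if r.alt else "-"
        svlen = len(r.alt) - len(r.ref)
        recs.append(dio.VcfLiteRecord(r.chrom, r.pos, "small_indel", ref, alt, {"SVLEN": svlen, "HAP": "B"}))
    dio.write_vcf_lite(out / "truth_small_variants.vcf", recs)

    sv_recs = [
        dio.VcfLiteRecord(
            r.chrom, r.start, r.category, "-", "-",
            {"SVTYPE": r.category, "SVLEN": r.size, "END": r.end, "HAP": "B"},
        )
        for r in genome.truth_svs.itertuples()
    ]
    dio.write_vcf_lite(out / "truth_svs.vcf", sv_recs)
    dio.write_bed(
        out / "truth_svs.bed",
        [
            dio.BedRecord(r.chrom, r.tract_start, max(r.tract_end, r.end), r.category, str(r.size), "+")
            for r in genome.truth_svs.itertuples()
        ],
    )
    dio.write_bed(
        out / "truth_repeats.bed",
        [dio.BedRecord(r.chrom, r.start, r.end, r.family) for r in genome.truth_repeats.itertuples()],
    )
    dio.write_gff3(
        out / "genes.gff3",
        [
            dio.Gff3Record(
                r.chrom, "diploscan", "gene", r.start, r.end, ".", r.strand, ".",
                f"ID={r.gene_id};truth_category={r.truth_category}",
            )
            for r in genome.genes.itertuples()
        ],
    )
    entries = {"seed": genome.config.seed}
    entries.update(genome.config.manifest_entries())
    dio.write_manifest(out / "manifest.tsv", entries)
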