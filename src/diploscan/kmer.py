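"""Exact canonical k-mer counting and k-mer based assembly QC.

The counter is an exact hash of 2-bit-encoded k-mers (contract: exact
counts, no sketching; 1 <= k <= 31 so a k-mer fits one uint64; for even k
a palindromic k-mer is its own canonical form). On top of the counter sit

* a two-peak genome-profile estimator (per-haplotype k-mer coverage,
  haploid length, heterozygosity, non-repetitive fraction, error rate),
* Merqury-style copy-number spectra, completeness and consensus QV,
* the missing-sequence length estimate, and
* missing-k-mer read rescue with the downstream contig filters.

A diploid read set shows two k-mer multiplicity peaks: heterozygous
k-mers occur on one haplotype only (coverage c), homozygous k-mers on
both (2c). The ratio of distinct k-mers under the two peaks gives the
per-base polymorphism rate; k-mers above the 2c window are repetitive.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

DEFAULT_K = 21
MAX_MULTIPLICITY = 1_000_000  # histogram depth cap; repeats stay included

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

# ------------------------------------------------------------------ encoding


def encode_bases(seq: str) -> np.ndarray:
    """2-bit base codes (A0 C1 G2 T3); anything else (incl. N) = 255."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(bases: np.ndarray, k: int) -> np.ndarray:
    """Forward-strand k-mer codes for every window free of non-ACGT bases."""
    n = bases.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = (bases == 255).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    codes = _rolling_codes(bases, k, n)
    return codes[valid]


def _rolling_codes(bases: np.ndarray, k: int, n: int) -> np.ndarray:
    b = np.where(bases == 255, 0, bases).astype(np.uint64)
    codes = b[:n].copy()
    two = np.uint64(2)
    for j in range(1, k):
        np.left_shift(codes, two, out=codes)
        np.bitwise_or(codes, b[j : j + n], out=codes)
    return codes


def kmer_codes_with_positions(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`kmer_codes` but also returns window start offsets."""
    n = bases.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    bad = (bases == 255).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    codes = _rolling_codes(bases, k, n)
    pos = np.nonzero(valid)[0].astype(np.int64)
    return codes[valid], pos


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    three = np.uint64(3)
    two = np.uint64(2)
    buf = np.empty_like(codes)
    for _ in range(k):
        np.left_shift(rc, two, out=rc)
        np.bitwise_and(tmp, three, out=buf)
        np.bitwise_xor(buf, three, out=buf)
        np.bitwise_or(rc, buf, out=rc)
        np.right_shift(tmp, two, out=tmp)
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical = lexicographic min of k-mer and its reverse complement."""
    return np.minimum(codes, revcomp_codes(codes, k))


def decode_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(int(code) >> (2 * (k - 1 - j))) & 3] for j in range(k))


# --------------------------------------------------------------------- store


@dataclasses.dataclass
class KmerSpectrum:
    """Histogram f: multiplicity m -> number of distinct canonical k-mers."""

    k: int
    hist: dict[int, int]

    @property
    def total_kmers(self) -> int:
        return int(sum(m * f for m, f in self.hist.items()))

    @property
    def distinct_kmers(self) -> int:
        return int(sum(self.hist.values()))

    def to_tsv(self, path) -> None:
        """GenomeScope-compatible histogram: multiplicity<TAB>count, no header."""
        with open(path, "w") as fh:
            for m in sorted(self.hist):
                fh.write(f"{m}\t{self.hist[m]}\n")

    @classmethod
    def from_tsv(cls, path, k: int = DEFAULT_K) -> "KmerSpectrum":
        hist = {}
        with open(path) as fh:
            for line in fh:
                m, f = line.split("\t")
                hist[int(m)] = int(f)
        return cls(k=k, hist=hist)


class KmerStore:
    """Sorted array of canonical k-mer codes with exact multiplicities."""

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray):
        self.k = k
        self.codes = codes
        self.counts = counts

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[str], k: int = DEFAULT_K, chunk_bases: int = 20_000_000
    ) -> "KmerStore":
        if not 1 <= k <= 31:
            raise ValueError(f"k must be in [1, 31], got {k}")
        acc_codes: list[np.ndarray] = []
        acc_counts: list[np.ndarray] = []
        buf: list[str] = []
        buffered = 0

        def flush():
            nonlocal buf, buffered
            if not buf:
                return
            bases = encode_bases("N".join(buf))
            codes = canonical_codes(kmer_codes(bases, k), k)
            u, c = np.unique(codes, return_counts=True)
            acc_codes.append(u)
            acc_counts.append(c.astype(np.int64))
            buf, buffered = [], 0

        for s in seqs:
            buf.append(s)
            buffered += len(s)
            if buffered >= chunk_bases:
                flush()
        flush()
        if not acc_codes:
            return cls(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
        allc = np.concatenate(acc_codes)
        alln = np.concatenate(acc_counts)
        u, inv = np.unique(allc, return_inverse=True)
        counts = np.zeros(u.size, dtype=np.int64)
        np.add.at(counts, inv, alln)
        return cls(k, u, counts)

    def merge(self, other: "KmerStore") -> "KmerStore":
        """Union store with per-k-mer multiplicities added."""
        if other.k != self.k:
            raise ValueError("k mismatch")
        allc = np.concatenate([self.codes, other.codes])
        alln = np.concatenate([self.counts, other.counts])
        u, inv = np.unique(allc, return_inverse=True)
        counts = np.zeros(u.size, dtype=np.int64)
        np.add.at(counts, inv, alln)
        return KmerStore(self.k, u, counts)

    # -- queries -----------------------------------------------------------

    @property
    def distinct_kmers(self) -> int:
        return int(self.codes.size)

    @property
    def total_kmers(self) -> int:
        return int(self.counts.sum())

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Multiplicity of each (canonical) code; 0 where absent."""
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.clip(idx, 0, max(self.codes.size - 1, 0))
        if self.codes.size == 0:
            return np.zeros(codes.size, dtype=np.int64)
        hit = self.codes[idx_c] == codes
        out = np.zeros(codes.size, dtype=np.int64)
        out[hit] = self.counts[idx_c[hit]]
        return out

    def contains(self, codes: np.ndarray) -> np.ndarray:
        return self.lookup(codes) > 0

    def missing_from(self, other: "KmerStore") -> "KmerStore":
        """Sub-store of k-mers in self that are absent from *other*."""
        mask = other.lookup(self.codes) == 0
        return KmerStore(self.k, self.codes[mask], self.counts[mask])

    def filter_min_count(self, min_count: int) -> "KmerStore":
        mask = self.counts >= min_count
        return KmerStore(self.k, self.codes[mask], self.counts[mask])

    def spectrum(self, max_multiplicity: int = MAX_MULTIPLICITY) -> KmerSpectrum:
        capped = np.minimum(self.counts, max_multiplicity)
        m, f = np.unique(capped, return_counts=True)
        return KmerSpectrum(self.k, {int(a): int(b) for a, b in zip(m, f)})


def count_kmers(seqs: Iterable[str] | dict[str, str], k: int = DEFAULT_K) -> KmerStore:
    """Exact canonical k-mer counts of a sequence collection.

    Windows containing non-ACGT characters are skipped; an empty input
    yields an empty store (not an error).
    """
    if isinstance(seqs, dict):
        seqs = seqs.values()
    return KmerStore.from_sequences(seqs, k=k)


# --------------------------------------------------------------- profile fit


@dataclasses.dataclass
class ProfileEstimate:
    """Two-peak k-mer profile fit.

    kcov
        per-haplotype k-mer coverage c (heterozygous-peak location).
    len_bp
        estimated haploid genome length.
    het
        estimated per-bp polymorphism rate, percent.
    uniq
        percent of the genome that is non-repetitive in k-mer space.
    err
        percent per-base read error rate.
    m0
        noise cutoff: first local minimum of the smoothed histogram.
    dup
        mean read duplication rate; not estimated by this model (None).
    """

    kcov: float
    len_bp: float
    het: float
    uniq: float
    err: float
    m0: int
    dup: float | None = None


def _smooth(f: np.ndarray, window: int = 3) -> np.ndarray:
    kern = np.ones(window) / window
    return np.convolve(f, kern, mode="same")


def profile_fit(
    spectrum: KmerSpectrum,
    homozygous: bool = False,
    w1_factor: float = 1.5,
    w2_factor: float = 2.5,
) -> ProfileEstimate:
    """Estimate genome parameters from a diploid read k-mer spectrum.

    Let m0 be the first local minimum of the smoothed histogram (error /
    signal split), c the heterozygous-peak coverage and
    W1 = (m0, 1.5c], W2 = (1.5c, 2.5c]. With D1, D2 the distinct-k-mer
    masses in the two windows, alpha = (D1/2) / (D1/2 + D2) is the
    probability that a genomic k-mer spans a polymorphism, so the per-base
    rate is het = 1 - (1 - alpha)^(1/k). The haploid length is the total
    signal k-mer mass divided by the homozygous coverage 2c, and
    uniq = (D1/2 + D2) / len. Requires >= ~15x per-haplotype coverage.
    """
    k = spectrum.k
    if not spectrum.hist:
        raise ValueError("empty spectrum")
    max_m = max(spectrum.hist)
    dense_top = min(max_m, 100_000)
    f = np.zeros(dense_top + 2, dtype=float)
    for m, cnt in spectrum.hist.items():
        if m <= dense_top:
            f[m] = cnt
    s = _smooth(f)

    # noise cutoff: first local minimum after m=1
    m0 = None
    for m in range(2, dense_top):
        if s[m] <= s[m - 1] and s[m] <= s[m + 1]:
            m0 = m
            break
    if m0 is None:
        raise ValueError("no local minimum in spectrum; peaks unresolvable")

    body = s[m0 + 1 :]
    if body.size < 3 or body.max() <= 0:
        raise ValueError("no signal above noise cutoff")
    peaks, _ = find_peaks(body, height=0.05 * body.max())
    peak_ms = peaks + m0 + 1
    if peak_ms.size == 0:
        peak_ms = np.array([int(np.argmax(body)) + m0 + 1])

    def refine(center: float) -> float:
        # centroid around the peak, two passes to re-center the window
        for _ in range(2):
            lo, hi = max(m0 + 1, int(0.7 * center)), min(dense_top, int(1.3 * center) + 2)
            w = s[lo:hi]
            if w.sum() > 0:
                center = float(np.sum(np.arange(lo, hi) * w) / w.sum())
        return center

    if homozygous:
        # single peak sits at 2c; refine around it, then halve
        two_c = refine(float(peak_ms[np.argmax(s[peak_ms])]))
        c = two_c / 2.0
    else:
        if peak_ms.size < 2:
            raise ValueError(
                "no heterozygous peak: spectrum is unimodal "
                "(pass homozygous=True for a homozygous sample)"
            )
        c = refine(float(peak_ms[0]))

    w1_hi = w1_factor * c
    w2_hi = w2_factor * c
    d1 = sum(cnt for m, cnt in spectrum.hist.items() if m0 < m <= w1_hi)
    d2 = sum(cnt for m, cnt in spectrum.hist.items() if w1_hi < m <= w2_hi)
    alpha = (d1 / 2.0) / (d1 / 2.0 + d2) if (d1 + d2) > 0 else 0.0
    het = 0.0 if homozygous else 100.0 * (1.0 - (1.0 - alpha) ** (1.0 / k))

    signal_mass = sum(m * cnt for m, cnt in spectrum.hist.items() if m > m0)
    len_bp = signal_mass / (2.0 * c)
    uniq = 100.0 * (d1 / 2.0 + d2) / len_bp if len_bp > 0 else 0.0

    m_err = sum(m * cnt for m, cnt in spectrum.hist.items() if m <= m0)
    m_tot = spectrum.total_kmers
    err = 100.0 * (1.0 - (1.0 - m_err / m_tot) ** (1.0 / k)) if m_tot else 0.0

    est = ProfileEstimate(kcov=c, len_bp=len_bp, het=het, uniq=uniq, err=err, m0=m0)
    two_c_peak = peak_ms[np.argmin(np.abs(peak_ms - 2 * c))] if peak_ms.size else 2 * c
    if not homozygous and abs(two_c_peak - 2 * c) > 0.25 * 2 * c:
        logger.warning("second peak at %s deviates >25%% from 2c=%s", two_c_peak, 2 * c)
    return est


# ------------------------------------------------------- copy-number spectra


@dataclasses.dataclass
class CopySpectrum:
    """Read k-mer histogram partitioned by assembly copy number.

    ``table`` columns: copies (0,1,2,3,4 meaning >=4), multiplicity, count.
    Class 0 ("missing") holds read k-mers absent from the assembly; mass at
    high multiplicity there indicates unassembled sequence.
    ``assembly_only`` counts distinct assembly k-mers unsupported by reads.
    """

    k: int
    table: pd.DataFrame
    assembly_only: int

    def row_hist(self, copies: int) -> dict[int, int]:
        sub = self.table[self.table["copies"] == copies]
        return dict(zip(sub["multiplicity"].astype(int), sub["count"].astype(int)))

    def read_spectrum(self) -> KmerSpectrum:
        agg = self.table.groupby("multiplicity")["count"].sum()
        return KmerSpectrum(self.k, {int(m): int(c) for m, c in agg.items()})

    def missing_spectrum(self) -> KmerSpectrum:
        return KmerSpectrum(self.k, self.row_hist(0))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, header=False)


def copy_spectra(read_store: KmerStore, assembly_store: KmerStore) -> CopySpectrum:
    """Classify each distinct read k-mer by its copy number in the assembly."""
    if read_store.k != assembly_store.k:
        raise ValueError("k mismatch between read and assembly stores")
    copies = np.minimum(assembly_store.lookup(read_store.codes), 4)
    mult = np.minimum(read_store.counts, MAX_MULTIPLICITY)
    df = (
        pd.DataFrame({"copies": copies, "multiplicity": mult})
        .groupby(["copies", "multiplicity"])
        .size()
        .rename("count")
        .reset_index()
    )
    asm_only = int((read_store.lookup(assembly_store.codes) == 0).sum())
    return CopySpectrum(read_store.k, df, asm_only)


# ------------------------------------------------------- completeness and QV


@dataclasses.dataclass
class AssemblyQC:
    completeness: float  # percent of reliable read k-mers present
    qv: float  # phred-scaled consensus accuracy, capped at 99
    missing_bp: float  # estimated unassembled sequence


QV_CAP = 99.0


def completeness_qv(read_store: KmerStore, assembly_store: KmerStore, m0: int) -> AssemblyQC:
    """Reference-free completeness and consensus QV.

    Reliable read k-mers are those with multiplicity >= m0 (the computed
    noise cutoff; never a hard-coded constant). Completeness is the percent
    of them present in the assembly. QV treats assembly k-mers unsupported
    by reads as errors: P = (1 - K_err/K_asm)^(1/k), qv = -10 log10(1 - P).
    """
    if assembly_store.distinct_kmers == 0:
        raise ValueError("empty assembly: completeness 0, QV undefined")
    reliable = read_store.filter_min_count(m0)
    n_rel = reliable.distinct_kmers
    present = int(assembly_store.contains(reliable.codes).sum())
    completeness = 100.0 * present / n_rel if n_rel else 0.0

    k_asm = assembly_store.total_kmers
    in_reads = read_store.contains(assembly_store.codes)
    k_err = int(assembly_store.counts[~in_reads].sum())
    if k_err == 0:
        qv = QV_CAP
    else:
        p = (1.0 - k_err / k_asm) ** (1.0 / read_store.k)
        qv = min(-10.0 * np.log10(1.0 - p), QV_CAP)

    missing = reliable.missing_from(assembly_store)
    missing_bp = missing_seq_estimate(missing.spectrum())
    return AssemblyQC(completeness=completeness, qv=float(qv), missing_bp=missing_bp)


def missing_seq_estimate(missing_spectrum: KmerSpectrum) -> float:
    """Length of sequence missing from an assembly, from its missing k-mers.

    Computed as (sum of k-mer counts x multiplicity) divided by the mean
    k-mer multiplicity of the distribution. Algebraically this equals the
    number of distinct missing k-mers; the formula is kept in its stated
    form and the equivalence is noted here and in reports.
    """
    total = sum(m * f for m, f in missing_spectrum.hist.items())
    distinct = sum(missing_spectrum.hist.values())
    if distinct == 0:
        return 0.0
    mean_mult = total / distinct
    return total / mean_mult


# --------------------------------------------------------------- read rescue


def rescue_reads(reads: Sequence, missing_store: KmerStore) -> list:
    """Reads containing at least one missing k-mer (canonical match).

    ``reads`` is any sequence of objects with a ``sequence`` attribute (or
    plain strings). The subset is deterministic and order-preserving.
    """
    if missing_store.distinct_kmers == 0:
        return []
    k = missing_store.k
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    selected = np.zeros(len(reads), dtype=bool)
    chunk = 200_000
    for start in range(0, len(seqs), chunk):
        block = seqs[start : start + chunk]
        joined = "N".join(block)
        bases = encode_bases(joined)
        codes, pos = kmer_codes_with_positions(bases, k)
        if codes.size == 0:
            continue
        codes = canonical_codes(codes, k)
        hit = missing_store.contains(codes)
        if not hit.any():
            continue
        # map window offsets back to read indices via separator layout
        starts = np.cumsum([0] + [len(s) + 1 for s in block[:-1]])
        ridx = np.searchsorted(starts, pos[hit], side="right") - 1
        selected[start + np.unique(ridx)] = True
    return [reads[i] for i in np.nonzero(selected)[0]]


def filter_rescued_contigs(
    contigs: Iterable[tuple[str, str, float]],
    min_cov: float = 10.0,
    min_len: int = 500,
) -> list[tuple[str, str, float]]:
    """Keep contigs with coverage >= min_cov and length >= min_len.

    Both thresholds are inclusive and configurable; defaults follow the
    short-read-contig filter of minimum 10x depth and 500 bp.
    """
    return [c for c in contigs if c[2] >= min_cov and len(c[1]) >= min_len]
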