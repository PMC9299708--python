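# Methods

This document records the model behind each module, how the preset
parameters were derived, the numerical choices that affect results, and the
known limitations of the generator and classifiers.

## 1. Synthetic diplome model (`simulate.py`)

### Backbone (hapA)

A haploid sequence of length *L* is built from uniform random DNA into which
repeat families are planted until the requested `repeat_fraction` of bases is
covered. Each family has a random unit (length drawn log-uniformly within
`repeat_unit_range`) and its copies are written with per-copy divergence
(`repeat_copy_divergence` substitutions per base), so repeat k-mers occur at
family-level multiplicity rather than as perfect duplicates. Copies of a
family are placed in loose clusters to mimic the blocky repeat landscape of a
real plant genome.

### Second haplotype (hapB)

hapB is derived from hapA by planting, in order: structural variants (from
`sv_counts`, sizes log-uniform within per-category ranges), heterozygous SNPs
(`het_snp_rate` per base) and small indels (`small_indel_rate`, 1–10 bp).
Every edit is recorded in a truth table with exact coordinates on both
sequences; `reconstruct_hapB()` replays the truth tables against hapA and is
asserted to reproduce hapB byte-for-byte. SV footprints are mutually
exclusive with a buffer of twice the SV size, and variant-free flanks of at
least the anchor seed length are preserved around every SV so each event is
resolvable by the scanner.

SV categories are generated with the geometry their names imply:

- **insertion / deletion** — novel sequence present on exactly one haplotype;
- **tandem expansion / contraction** — a 2-copy tandem array becomes 4 copies
  (or the reverse), so the query-vs-reference overlap of the flanking anchors
  is approximately the event size;
- **repeat expansion / contraction** — a 2-copy array becomes 5 copies (or
  the reverse), so the overlap (2 units) differs from the event size
  (3 units).

Genes with an `ase_sv_linked_fraction` of the complete-ASE genes get a large
INDEL planted within 5 kb (a "linked" INDEL). The linked-INDEL window is
first tried against the buffered exclusion mask; if a neighbouring SV's
buffer covers the whole window, placement falls back to a relaxed mask that
blocks only actual SV footprints plus a 300 bp margin. This keeps linked
placement feasible at high SV density without ever overlapping two events.

### Reads, assembly, expression, linkage map

Reads are error-free fixed-length fragments sampled uniformly from both
haplotypes at `coverage` per haplotype. The assembly is produced by
`fragment_into_contigs`: hapA is Poisson-fragmented into primaries; hapB is
reduced to its heterozygous segments (maximal variant runs merged within
`het_collapse_gap`), a `haplotig_drop_fraction` of which is withheld, and the
kept segments are fragmented into haplotigs. Allelic expression counts are
binomial draws per gene and tissue whose allele ratio depends on the gene's
truth category (complete ≈ 0.985 major-allele fraction, partial ≈ 0.75,
none = 0.5). The linkage map tabulates evenly spaced markers with genetic
positions proportional to physical position per linkage group.

### Presets

`tme7_preset(length, seed, …)` scales the reference scenario down to the
requested length:

- heterozygosity 1.41 % split ~10:1 between SNPs and small indels
  (`het_snp_rate = 0.012818`, `small_indel_rate = 0.0012818`; one indel event
  contributes ~1 het base for spectrum purposes);
- `repeat_fraction = 0.61`;
- SV counts proportioned like the reference difference table over the six
  categories, scaled by `length`.

`divergence_preset(length, seed)` targets 2.09 % alignment divergence. With
SNP rate *s* and mean small-indel length ~5.5 at rate *s*/10, divergence is
approximately `s(1 + 0.1·mean_len) / (1 + 0.05·s·mean_len)` (numerator:
mismatches plus indel bases per reference base; denominator: alignment
columns per reference base). Solving for the 2.09 % target gives
*s* ≈ 0.013975.

## 2. k-mer profile (`kmer.py`)

Canonical k-mers are encoded as 2-bit-packed uint64 codes and counted exactly
with `numpy.unique`. The spectrum fit:

- the error boundary `m0` is the first local minimum of the spectrum;
- the haploid peak is located as the argmax above `m0` and refined by a
  two-pass weighted centroid over a window around it, giving the k-mer
  coverage `c_k`; the expected relation to base coverage is
  `c_k = c·(L−k+1)/L`;
- distinct k-mers with multiplicity in (m0, 1.5·c_k] are heterozygous, those
  in (1.5·c_k, 2.5·c_k] homozygous-unique, those above repetitive; with α the
  heterozygous fraction of distinct k-mers, heterozygosity is
  `100·(1 − (1−α)^(1/k))` — the per-base rate whose k-mer-level footprint is
  α;
- haploid length is total non-error k-mer mass divided by `2·c_k`;
- completeness is the fraction of distinct non-error read k-mers present in
  the assembly; QV is `−10·log10` of the inferred per-base error rate from
  assembly k-mers absent in the reads, capped at 99.

## 3. Purge classification (`purge.py`)

`DepthCutoffs` is the sextuple (junk_max, het_lo, het_peak, het_hi, dip_hi,
repeat_max); the template (5, 76, 126, 151, 252, 453) is rescaled to the
observed k-mer coverage with `.scaled(kcov)` (linear in kcov, rounded,
forced strictly ascending). Classification rule per contig:

1. mean depth ≤ junk_max → **JUNK**;
2. mean depth > repeat_max → **REPEAT**;
3. mean depth ≤ het_hi *and* the contig aligns to some strictly longer
   contig with aligned fraction ≥ 0.8 at ≥ 90 % identity → **HAPLOTIG**
   (alignment intervals on the contig are merged before computing the
   fraction);
4. otherwise → **PRIMARY**.

Haplotig→primary association takes, per haplotig, the target with the most
aligned bases; ties break on the natural sort key of the target name
(`p2 < p10`). `place_full_length` extends the best chain's target span by
the haplotig's unaligned prefix/suffix, clipped to the target bounds, so the
whole haplotig is assigned coordinates, not just its aligned core.

## 4. SV scanning (`svscan.py`)

Anchors are k-mers unique in both sequences (seed length `min_seed`, default
100 via merged unique matches), chained collinearly per strand. For each
inter-anchor gap the reference-gap/query-gap pair (rgap, qgap) decides the
call:

- both gaps ≤ `small_indel_max` (50): counted into the per-chain SNP/small
  indel tallies via banded edlib alignment, not called as an SV;
- rgap ≈ 0 < qgap → **insertion**; qgap ≈ 0 < rgap → **deletion** (size =
  the larger gap, after slop);
- negative gap (anchor overlap) on one side → copy-number change: with
  overlap *v* and size *d*, `|v − d| ≤ 0.1·d` → **tandem**
  expansion/contraction, otherwise **repeat** expansion/contraction.

If a chance sequence extension makes a small negative gap
(0 < −min(rgap,qgap) < `small_indel_max`), the overlap is trimmed back into
the gap (anchor matched bases and columns decremented accordingly) so that
small indels adjacent to anchor-extendable sequence are still counted; this
was validated against an independent full-dynamic-programming edlib oracle.

Divergence per chain is `(mismatches + indel bases) / aligned columns` over
anchor bases plus aligned gap columns; gaps > 1 kb are excluded from the
divergence denominator. The report's mean is aligned-bp-weighted across
chains. Summary bins are 50–500 bp (50 inclusive, 500 exclusive on the lower
bin) and 500–10 000 bp (10 000 inclusive); `SVSummary.from_cells` builds a
summary directly from (count, bp) cells for table arithmetic.

Truth matching in tests uses: same category, size within ±10 bp, call
coordinate within [tract_start − 300, max(tract_end, end) + 300] — the
±300 bp slack absorbs anchor-boundary ambiguity inside repeat tracts.

## 5. Allele-specific expression (`ase.py`)

Per gene × tissue, an exact binomial test of refCount vs 0.5 (p = 1.0 when
the total is 0), Benjamini–Hochberg correction **within tissue**,
significance at padj < 0.05. Significant genes with |log2(alt/ref)| ≥ 5 are
**complete** (consistent with a silenced allele at sequencing depth ~100;
pseudocount 0.5), others **partial**; non-significant genes are **none**.
Gene-level category over tissues: all-complete → complete, all-none → none,
otherwise partial. `allelic_pca` runs PCA on variance-stabilized counts and
on log2 fold changes (requires ≥ 3 samples). `proximity_ks` runs two-sample
Kolmogorov–Smirnov tests on |distance to nearest INDEL| between gene
categories per direction; comparisons with fewer than 5 genes on either side
are flagged `skipped` (NaN distances are dropped first).

## 6. Linkage-map validation (`linkmap.py`)

Each marker becomes a 201 nt tag centred on its (1-based) source position,
clipped at sequence ends. Tags are aligned to the assembly; hits are kept
only with aligned length strictly > 150 and identity strictly > 95 %.
Markers with one kept hit are **unique**, several **duplicate**, none
**unplaced**. Per linkage group (≥ 3 unique markers on its majority target),
collinearity is the Spearman |rho| between genetic and physical position;
the report's mean is over qualifying groups.

## 7. Pipeline (`pipeline.py`, `cli.py`)

Stages run in the fixed order simulate → kprofile → purge → svscan → ase →
linkmap; ase depends on simulate and svscan, and dependents of a failed
stage are skipped, not run. A `RunManifest` records the config, per-stage
status/timing and SHA-256 checksums of all outputs. JSON is strict
(`allow_nan=False`; NaN sanitized to null before dumping). INI configs
reject unknown sections and keys with `ValueError`. When the gene count is
not given it defaults to `length // 20_000`, a density at which placement of
genes plus linked INDELs is reliably feasible across seeds.

## 8. Reference-scale targets (`targets.py`)

Each target simulates fresh data (see module docstring): t5/t6 from a 1 Mb
`tme7_preset` read spectrum; t7 as the aligned-bp-weighted divergence over
50 independent 100 kb `divergence_preset` pairs; t8 on 2000 genes × 3
tissues with the truth category mix of the preset (expected significant
share ≈ complete 5 % + partial 15 % ≈ 20 %); t9 on 600 genes, half
complete-ASE with all of them INDEL-linked, comparing complete vs none
distance distributions (best direction, KS). `compute_all` derives four
independent sub-seeds from the master seed with `default_rng(seed)`.

## Limitations

- Reads are error-free and uniform; the error peak in the spectrum comes
  only from fragment-junction effects, so `err_pct` is near zero and QV
  saturates at its cap on perfect assemblies.
- Dispersed new repeat copies (far from the source array) present to the
  scanner as plain insertions and are classified as such; only adjacent
  copy-number changes are recoverable as repeat/tandem events from anchor
  geometry alone.
- The purge containment rule requires a strictly longer target, so a
  haplotig spanning a primary-fragment boundary may stay PRIMARY; real
  purging tools use the same conservative behaviour for split alignments.
- Haplotig fragmentation loses k-mers at fragment junctions, so assembly
  completeness is slightly below 100 % even with no dropped segments.
- The ASE read-count model is binomial per gene × tissue with fixed
  category ratios; there is no overdispersion or mapping bias.
- Genetic map positions are strictly proportional to physical positions, so
  |rho| = 1 is the expected value for a faithful assembly; the statistic is
  meaningful only for detecting misjoins/inversions introduced downstream.
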