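"""End-to-end orchestration: simulate -> profile -> purge -> svscan -> ase
-> linkmap, with a machine-readable run manifest.

Configuration is flat INI text (key = value within named sections), so a
run is diff-able and hashable; the resolved configuration, the seed, every
stage's wall-clock time and the checksum of every output file are echoed
into the manifest. A failed stage halts its dependents while independent
stages continue; the process exit status is non-zero if any stage failed.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import io as dio
from . import kmer as kmer_mod
from . import linkmap as linkmap_mod
from . import purge as purge_mod
from . import simulate as sim_mod
from . import svscan as sv_mod

logger = logging.getLogger(__name__)


def _json_sanitize(obj):
    """Make report objects strictly JSON: NaN -> null, numpy -> python."""
    if isinstance(obj, dict):
        return {k: _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return None if np.isnan(obj) else float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_json_sanitize(obj), fh, indent=1, allow_nan=False)

STAGES = ("simulate", "kprofile", "purge", "svscan", "ase", "linkmap")
DEPENDENCIES = {
    "simulate": (),
    "kprofile": ("simulate",),
    "purge": ("simulate",),
    "svscan": ("simulate",),
    "ase": ("simulate", "svscan"),
    "linkmap": ("simulate",),
}

_KNOWN_KEYS = {
    "run": {"out_dir", "seed", "stages"},
    "simulate": {"preset", "length", "n_genes", "n_tissues", "coverage", "read_length",
                 "read_error_rate", "n50_target", "drop_het_fraction"},
    "kprofile": {"k", "max_multiplicity"},
    "purge": {"cutoffs", "min_hap_align_frac", "min_identity"},
    "svscan": {"min_size", "max_size", "min_seed", "min_cluster"},
    "ase": {"alpha", "lfc_threshold", "min_total"},
    "linkmap": {"n_markers", "flank", "min_len", "min_ident"},
}


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "diploscan_run"
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    # simulate
    preset: str = "tme7"
    length: int = 500_000
    n_genes: int = 0  # 0 = auto: length // 20_000 (leaves packing headroom in the ~39% unique fraction)
    n_tissues: int = 3
    coverage: float = 40.0
    read_length: int = 150
    read_error_rate: float = 0.0
    n50_target: int = 50_000
    drop_het_fraction: float = 0.0
    # kprofile
    k: int = 21
    max_multiplicity: int = 1_000_000
    # purge
    cutoffs: str = "auto"
    min_hap_align_frac: float = 0.8
    min_identity: float = 90.0
    # svscan
    min_size: int = 50
    max_size: int = 10_000
    min_seed: int = 100
    min_cluster: int = 500
    # ase
    alpha: float = 0.05
    lfc_threshold: float = 5.0
    min_total: int = 10
    # linkmap
    n_markers: int = 200
    flank: int = 100
    min_len: int = 150
    min_ident: float = 95.0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        if not Path(path).is_file():
            raise FileNotFoundError(f"config file not found: {path}")
        parser = configparser.ConfigParser()
        parser.read(str(path))
        cfg = cls()
        for section in parser.sections():
            if section not in _KNOWN_KEYS:
                raise ValueError(f"unknown config section [{section}]")
            for key, value in parser.items(section):
                if key not in _KNOWN_KEYS[section]:
                    raise ValueError(f"unknown key '{key}' in section [{section}]")
                if key == "stages":
                    cfg.stages = tuple(s.strip() for s in value.split(","))
                    continue
                current = getattr(cfg, key)
                typ = type(current)
                setattr(cfg, key, typ(value) if typ is not str else value)
        return cfg

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stage_status: dict
    stage_seconds: dict
    checksums: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


class _Context(dict):
    """Shared objects passed between stages."""


# ------------------------------------------------------------------- stages


def _stage_simulate(cfg: PipelineConfig, out: Path, ctx: _Context) -> None:
    if cfg.preset == "tme7":
        sim = sim_mod.tme7_preset(
            haploid_length=cfg.length, seed=cfg.seed,
            n_genes=cfg.n_genes or cfg.length // 20_000,
            n_tissues=cfg.n_tissues, coverage_per_haplotype=cfg.coverage,
            read_length=cfg.read_length, read_error_rate=cfg.read_error_rate,
        )
    else:
        raise ValueError(f"unknown preset '{cfg.preset}'")
    genome = sim_mod.generate_diploid(sim)
    ctx["genome"] = genome
    sim_mod.write_genome_outputs(genome, out)
    reads = sim_mod.simulate_reads(genome)
    ctx["reads"] = reads
    reads.to_fastq(out / "reads.fastq")
    frag = sim_mod.fragment_into_contigs(genome, cfg.n50_target, cfg.drop_het_fraction)
    ctx["frag"] = frag
    dio.write_fasta(out / "primaries.fasta", frag.primaries)
    dio.write_fasta(out / "haplotigs.fasta", frag.haplotigs)
    depths = sim_mod.simulate_depths(frag, genome)
    ctx["depths"] = depths
    dio.write_tsv(out / "depths.tsv", depths)
    counts = sim_mod.simulate_allelic_counts(genome)
    ctx["allelic_counts"] = counts
    dio.write_tsv(out / "allelic_counts.tsv", counts)
    markers = sim_mod.simulate_linkage_map(genome)
    ctx["markers"] = markers
    dio.write_tsv(out / "linkage_map.tsv", markers)


def _stage_kprofile(cfg: PipelineConfig, out: Path, ctx: _Context) -> None:
    reads = ctx["reads"]
    frag = ctx["frag"]
    read_store = kmer_mod.count_kmers(reads.sequences, cfg.k)
    read_store.spectrum(cfg.max_multiplicity).to_tsv(out / "read_spectrum.tsv")
    est = kmer_mod.profile_fit(read_store.spectrum(cfg.max_multiplicity))
    ctx["profile"] = est
    asm_store = kmer_mod.count_kmers(frag.all_contigs(), cfg.k)
    cspec = kmer_mod.copy_spectra(read_store, asm_store)
    cspec.to_tsv(out / "copy_spectrum.tsv")
    qc = kmer_mod.completeness_qv(read_store, asm_store, est.m0)
    report = {
        "kcov": est.kcov, "len_bp": est.len_bp, "het_pct": est.het,
        "uniq_pct": est.uniq, "err_pct": est.err, "m0": est.m0,
        "dup": None,  # mean read duplication rate: not estimated by this model
        "completeness_pct": qc.completeness, "qv": qc.qv,
        # the missing-length formula reduces to the distinct missing k-mer count
        "missing_bp": qc.missing_bp,
    }
    _dump_json(report, out / "profile.json")


def _stage_purge(cfg: PipelineConfig, out: Path, ctx: _Context) -> None:
    frag = ctx["frag"]
    genome = ctx["genome"]
    chains = sv_mod.anchor_align(frag.primaries, frag.haplotigs)
    paf = sv_mod.chains_to_paf(chains, frag.primaries, frag.haplotigs)
    dio.write_paf(out / "haplotig_alignments.paf", paf)
    if cfg.cutoffs == "auto":
        cuts = purge_mod.DepthCutoffs.scaled(genome.config.coverage_per_haplotype)
    else:
        cuts = purge_mod.DepthCutoffs.from_string(cfg.cutoffs)
    classes = purge_mod.classify_contigs(
        frag.all_contigs(), ctx["depths"], paf, cuts,
        min_hap_align_frac=cfg.min_hap_align_frac, min_identity=cfg.min_identity,
    )
    dio.write_tsv(out / "classification.tsv", classes)
    assoc = purge_mod.associate_haplotigs(list(frag.haplotigs), paf)
    dio.write_tsv(out / "associations.tsv", assoc)
    renames = purge_mod.rename_haplotigs(assoc)
    renamed = {renames.get(k, k): v for k, v in frag.haplotigs.items()}
    dio.write_fasta(out / "haplotigs_renamed.fasta", renamed)
    best = sv_mod.best_chain_per_query(chains)
    placements = [purge_mod.place_full_length(ch) for ch in best.values()]
    dio.write_bed(out / "placements.bed", purge_mod.placements_to_bed(placements))
    ctx["placements"] = placements


def _stage_svscan(cfg: PipelineConfig, out: Path, ctx: _Context) -> None:
    genome = ctx["genome"]
    chains = sv_mod.anchor_align(
        genome.hapA, genome.hapB, min_seed=cfg.min_seed, min_cluster=cfg.min_cluster
    )
    best = sv_mod.best_chain_per_query(chains)
    records = []
    for ch in best.values():
        records.extend(
            sv_mod.classify_between_anchors(ch, min_size=cfg.min_size, max_size=cfg.max_size)
        )
    ctx["sv_records"] = records
    dio.write_bed(out / "sv_calls.bed", sv_mod.sv_records_to_bed(records))
    dio.write_vcf_lite(out / "sv_calls.vcf", sv_mod.sv_records_to_vcf(records))
    summary = sv_mod.summarize_svs(records)
    summary.to_tsv(out / "sv_summary.tsv")
    tally = sv_mod.within_alignment_variants(list(best.values()), genome.hapA, genome.hapB)
    div = sv_mod.haplotype_divergence(chains, genome.hapA, genome.hapB)
    _dump_json(
        {
            "mean_divergence_pct": div.mean, "sd": div.sd, "aligned_bp": div.aligned_bp,
            "snp_count": tally.snp_count, "small_indel_bases": tally.indel_bases,
        },
        out / "divergence.json",
    )


def _stage_ase(cfg: PipelineConfig, out: Path, ctx: _Context) -> None:
    genome = ctx["genome"]
    counts = ctx["allelic_counts"]
    results = ase_mod.test_ase(
        counts, alpha=cfg.alpha, lfc_threshold=cfg.lfc_threshold, min_total=cfg.min_total
    )
    dio.write_tsv(out / "ase_results.tsv", results)
    dio.write_tsv(out / "ase_fractions.tsv", ase_mod.categorize(results))
    sharing = ase_mod.tissue_sharing(results)
    gene_cats = ase_mod.gene_level_categories(results)
    indels = pd.DataFrame(
        [
            (r.ref_id, r.ref_start, max(r.ref_end, r.ref_start + r.size))
            for r in ctx["sv_records"]
            if r.category in ("insertion", "deletion")
        ],
        columns=["chrom", "start", "end"],
    )
    genes = genome.genes.set_index("gene_id")
    distances = {
        d: sv_mod.distance_to_features(genes, indels, d) for d in ("upstream", "downstream")
    }
    prox = ase_mod.proximity_ks(gene_cats, distances)
    report = {
        "n_all_tissues": sharing["n_all_tissues"],
        "n_exactly_one": sharing["n_exactly_one"],
        "proximity": prox.table.to_dict(orient="records"),
        "test": "exact binomial on allelic split, BH within tissue",
    }
    _dump_json(report, out / "ase_report.json")
    if genome.config.n_tissues >= 3 and not results.empty:
        pcas = ase_mod.allelic_pca(results)
        for name, res in pcas.items():
            res.coordinates.to_csv(out / f"pca_{name}.tsv", sep="\t")


def _stage_linkmap(cfg: PipelineConfig, out: Path, ctx: _Context) -> None:
    genome = ctx["genome"]
    markers = ctx["markers"]
    tags = linkmap_mod.extract_marker_tags(markers, genome.hapA, flank=cfg.flank)
    dio.write_fasta(out / "marker_tags.fasta", dict(zip(tags["marker"], tags["tag"])))
    hits = linkmap_mod.align_filter_tags(
        tags, genome.hapA, min_len=cfg.min_len, min_ident=cfg.min_ident
    )
    dio.write_tsv(out / "tag_hits.tsv", hits)
    report = linkmap_mod.collinearity(markers, hits)
    dio.write_tsv(out / "collinearity.tsv", report.per_group)
    _dump_json(report.to_json_dict(), out / "collinearity.json")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "kprofile": _stage_kprofile,
    "purge": _stage_purge,
    "svscan": _stage_svscan,
    "ase": _stage_ase,
    "linkmap": _stage_linkmap,
}


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Run the enabled stages in dependency order.

    A failing stage marks its dependents "skipped" while independent stages
    continue. Returns the manifest (also written to the output directory);
    callers should exit non-zero if any stage failed.
    """
    from . import __version__

    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    ctx = _Context()
    status: dict[str, str] = {}
    seconds: dict[str, float] = {}
    enabled = [s for s in STAGES if s in cfg.stages]
    for stage in enabled:
        if any(status.get(dep) in ("failed", "skipped") for dep in DEPENDENCIES[stage]):
            status[stage] = "skipped"
            logger.warning("stage %s skipped (failed dependency)", stage)
            continue
        stage_dir = out_root / stage
        stage_dir.mkdir(exist_ok=True)
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](cfg, stage_dir, ctx)
            status[stage] = "ok"
        except Exception:
            logger.exception("stage %s failed", stage)
            status[stage] = "failed"
        seconds[stage] = round(time.time() - t0, 3)

    checksums = {
        str(p.relative_to(out_root)): dio.sha256_of(p)
        for p in dio.iter_output_files(out_root)
        if p.name != "manifest.json"
    }
    manifest = RunManifest(
        version=__version__,
        config_hash=cfg.hash(),
        seed=cfg.seed,
        stage_status=status,
        stage_seconds=seconds,
        checksums=checksums,
    )
    manifest.write(out_root / "manifest.json")
    return manifest
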