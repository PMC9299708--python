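"""Readers and writers for the text formats the pipeline exchanges.

Internally every interval is 0-based half-open; GFF3 and VCF-lite are
1-based on disk (standard conventions), BED and PAF are 0-based half-open.
Parse -> write -> parse is the identity on records.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------- FASTA/FASTQ


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str], wrap: int = 80) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ as (id, sequence, quality-string) tuples."""
    out = []
    with open(path) as fh:
        for rec in SeqIO.QualityIO.FastqGeneralIterator(fh):
            out.append(rec)
    return out


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ------------------------------------------------------------------------ BED


@dataclasses.dataclass
class BedRecord:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    name: str = "."
    score: str = "."
    strand: str = "."


def read_bed(path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            records.append(
                BedRecord(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[3] if len(f) > 3 else ".",
                    f[4] if len(f) > 4 else ".",
                    f[5] if len(f) > 5 else ".",
                )
            )
    return records


def write_bed(path, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


# ----------------------------------------------------------------------- GFF3


@dataclasses.dataclass
class Gff3Record:
    seqid: str
    source: str
    type: str
    start: int  # 0-based half-open internally
    end: int
    score: str
    strand: str
    phase: str
    attributes: str


def read_gff3(path) -> list[Gff3Record]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            records.append(
                Gff3Record(f[0], f[1], f[2], int(f[3]) - 1, int(f[4]), f[5], f[6], f[7], f[8])
            )
    return records


def write_gff3(path, records: Iterable[Gff3Record]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                f"{r.seqid}\t{r.source}\t{r.type}\t{r.start + 1}\t{r.end}\t"
                f"{r.score}\t{r.strand}\t{r.phase}\t{r.attributes}\n"
            )


# ------------------------------------------------------------------- VCF-lite
# Minimal VCF dialect for truth variants and SV calls: fixed 8 columns,
# INFO keys SVTYPE / SVLEN / HAP / END only.


@dataclasses.dataclass
class VcfLiteRecord:
    chrom: str
    pos: int  # 0-based internally
    id: str
    ref: str
    alt: str
    info: dict


_INFO_INT_KEYS = {"SVLEN", "END"}


def read_vcf_lite(path) -> list[VcfLiteRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            info = {}
            if f[7] != ".":
                for kv in f[7].split(";"):
                    k, _, v = kv.partition("=")
                    info[k] = int(v) if k in _INFO_INT_KEYS else v
            records.append(VcfLiteRecord(f[0], int(f[1]) - 1, f[2], f[3], f[4], info))
    return records


def write_vcf_lite(path, records: Iterable[VcfLiteRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            info = ";".join(f"{k}={v}" for k, v in r.info.items()) or "."
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.id}\t{r.ref}\t{r.alt}\t.\t.\t{info}\n")


# ------------------------------------------------------------------------ PAF


@dataclasses.dataclass
class PafRecord:
    query: str
    query_len: int
    query_start: int  # 0-based half-open, always on the original query strand
    query_end: int
    strand: str
    target: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int = 255

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / max(self.block_len, 1)


def read_paf(path) -> list[PafRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            records.append(
                PafRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                    f[5], int(f[6]), int(f[7]), int(f[8]),
                    int(f[9]), int(f[10]), int(f[11]),
                )
            )
    return records


def write_paf(path, records: Iterable[PafRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query}\t{r.query_len}\t{r.query_start}\t{r.query_end}\t{r.strand}\t"
                f"{r.target}\t{r.target_len}\t{r.target_start}\t{r.target_end}\t"
                f"{r.matches}\t{r.block_len}\t{r.mapq}\n"
            )


# ------------------------------------------------------------------ TSV utils


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path, entries: dict) -> None:
    """Run manifest as two-column key<TAB>value TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in entries.items():
            fh.write(f"{k}\t{v}\n")


def read_manifest(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            k, _, v = line.rstrip("\n").partition("\t")
            out[k] = v
    return out


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def iter_output_files(directory) -> Iterator[Path]:
    return (p for p in sorted(Path(directory).rglob("*")) if p.is_file())
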