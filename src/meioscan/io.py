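"""File formats and run configuration.

FASTA/FASTQ go through Biopython, VCF through pysam, BED/TSV through
pandas. Coordinates are 0-based half-open in memory and 1-based in VCF.
Deletion calls use an anchor-base REF/ALT representation up to 50 bp and a
symbolic ``<DEL>`` record with an END info key above that.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._encode import decode, encode
from .delscan import DeletionCall
from .synthgenome import ReadSet, ReadSimParams, ReferenceGenome, SnpTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_snp_vcf",
    "write_snp_vcf",
    "read_allele_vcf",
    "read_deletion_vcf",
    "write_deletion_vcf",
    "read_bed",
    "write_bed",
    "save_yaml",
    "load_yaml",
    "config_hash",
    "write_manifest",
]

SYMBOLIC_DEL_MIN = 51  # anchor-base representation up to 50 bp


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(genome, path) -> None:
    """Write a genome dict (chrom -> codes) or ReferenceGenome to FASTA."""
    if isinstance(genome, ReferenceGenome):
        items = [(n, genome.seqs[n]) for n in genome.names]
    else:
        items = list(genome.items())
    records = [SeqRecord(Seq(decode(seq)), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, np.ndarray]:
    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: ReadSet, path1, path2) -> None:
    qual = [reads.params.base_qual] * reads.params.read_len
    for path, mat in ((path1, reads.r1), (path2, reads.r2)):
        records = []
        for i in range(len(reads)):
            rec = SeqRecord(Seq(decode(mat[i])), id=reads.read_id(i), description="")
            rec.letter_annotations["phred_quality"] = qual
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")


def read_fastq(path1, path2, insert_mean: float = 400.0, insert_sd: float = 40.0) -> ReadSet:
    def load(path):
        return np.vstack([encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")])

    r1, r2 = load(path1), load(path2)
    if r1.shape != r2.shape:
        raise ValueError("mate files differ in read count or length")
    params = ReadSimParams(
        read_len=r1.shape[1], insert_mean=insert_mean, insert_sd=insert_sd
    )
    return ReadSet(r1=r1, r2=r2, params=params)


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_meta(
        "INFO", items=[("ID", "END"), ("Number", 1), ("Type", "Integer"), ("Description", "End position")]
    )
    header.add_meta(
        "INFO", items=[("ID", "SVTYPE"), ("Number", 1), ("Type", "String"), ("Description", "SV type")]
    )
    header.add_meta(
        "INFO", items=[("ID", "SVLEN"), ("Number", 1), ("Type", "Integer"), ("Description", "SV length")]
    )
    header.add_meta(
        "INFO",
        items=[("ID", "SUPPORT"), ("Number", 1), ("Type", "Integer"), ("Description", "Supporting reads")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "EVIDENCE"), ("Number", 1), ("Type", "String"), ("Description", "Evidence class")],
    )
    return header


def write_snp_vcf(snps: SnpTable, ref: ReferenceGenome, path) -> None:
    """Phased parental markers: REF = parent-A allele, ALT = parent-B allele."""
    header = _vcf_header({n: ref.length(n) for n in ref.names})
    header.add_meta("meioscan_mean_spacing", str(snps.mean_spacing))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in snps.df.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=int(row.pos), alleles=(row.allele_a, row.allele_b)
            )
            out.write(rec)


def read_snp_vcf(path) -> SnpTable:
    rows = []
    mean_spacing = None
    with pysam.VariantFile(str(path)) as vf:
        for line in str(vf.header).splitlines():
            if line.startswith("##meioscan_mean_spacing="):
                mean_spacing = float(line.split("=", 1)[1])
        for rec in vf:
            rows.append((rec.contig, rec.start, rec.ref, rec.alts[0]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b"])
    if mean_spacing is None:
        gaps = df.groupby("chrom")["pos"].diff().dropna()
        mean_spacing = float(gaps.mean()) if len(gaps) else 500.0
    return SnpTable(df, mean_spacing)


def read_allele_vcf(path) -> pd.DataFrame:
    """Observed offspring alleles as a genotype frame (chrom, pos, allele).

    The first ALT allele is taken when present, the REF allele otherwise;
    pair with a parental SnpTable via ``informative_markers``.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            allele = rec.alts[0] if rec.alts else rec.ref
            rows.append((rec.contig, rec.start, allele))
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele"])


def write_deletion_vcf(calls: list[DeletionCall], ref: ReferenceGenome, path) -> None:
    """Deletion calls; anchor-base records below SYMBOLIC_DEL_MIN bp, else <DEL>."""
    header = _vcf_header({n: ref.length(n) for n in ref.names})
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            seq = ref.seqs[c.chrom]
            anchor = max(0, c.start - 1)
            anchor_base = decode(seq[anchor : anchor + 1])
            if c.size < SYMBOLIC_DEL_MIN and c.start >= 1:
                alleles = (anchor_base + decode(seq[c.start : c.end]), anchor_base)
                rec = out.new_record(contig=c.chrom, start=anchor, alleles=alleles)
            else:
                rec = out.new_record(
                    contig=c.chrom, start=anchor, alleles=(anchor_base, "<DEL>"), stop=c.end
                )
                rec.info["SVTYPE"] = "DEL"
                rec.info["SVLEN"] = -c.size
            rec.info["SUPPORT"] = c.n_support
            rec.info["EVIDENCE"] = c.evidence
            out.write(rec)


def read_deletion_vcf(path) -> list[DeletionCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            support = int(rec.info.get("SUPPORT", 1))
            evidence = str(rec.info.get("EVIDENCE", "gapped"))
            if rec.alts and rec.alts[0] == "<DEL>":
                start, end = rec.start + 1, rec.stop
            else:
                start = rec.start + 1
                end = rec.start + len(rec.ref)
            calls.append(
                DeletionCall(rec.contig, start, end, end - start, evidence, support)
            )
    return calls


# ---------------------------------------------------------------------------
# BED


def write_bed(df: pd.DataFrame, path) -> None:
    """Write chrom/start/end (+ extra columns) as headerless BED."""
    cols = ["chrom", "start", "end"]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_names=()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_names]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(len(names), df.shape[1])]
    if (df["end"] < df["start"]).any():
        raise ValueError("BED end < start")
    return df


# ---------------------------------------------------------------------------
# config / manifest


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_yaml(config, path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(config), sort_keys=True))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def config_hash(config) -> str:
    return hashlib.sha256(
        json.dumps(_plain(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def write_manifest(outdir, config, seed: int) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(seed), "config_hash": config_hash(config), "config": _plain(config)}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
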