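"""Readers/writers for the plain-text formats the pipeline exchanges.

SAM/BAM and VCF reading go through pysam elsewhere; writers here emit the
small, deterministic text files the simulators and trackers produce
(60-column FASTA, bedGraph, BED, TSV, VCFv4.2).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def write_fasta(path, records, width: int = 60) -> None:
    """records: iterable of (name, sequence-str)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    """Whole-file FASTA -> {name: sequence} (upper-cased)."""
    seqs: dict[str, list] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_bed(path, intervals, extra_cols=None) -> None:
    """intervals: iterable of (chrom, start, end[, *rest])."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return rows


def write_chrom_sizes(path, chrom_lengths: dict) -> None:
    with open(path, "w") as fh:
        for c, l in chrom_lengths.items():
            fh.write(f"{c}\t{l}\n")


def read_chrom_sizes(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c, l = line.split()[:2]
                out[c] = int(l)
    return out


def write_manifest(path, samples) -> None:
    """samples: list of dicts with sample_id, sex, fastq1[, fastq2]."""
    Path(path).write_text(json.dumps(samples, indent=2) + "\n")


def read_manifest(path):
    p = Path(path)
    if p.suffix == ".json":
        return json.loads(p.read_text())
    samples = []
    with open(p) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: manifest needs sample_id, sex, fastq1")
            rec = {"sample_id": parts[0], "sex": parts[1], "fastq1": parts[2]}
            if len(parts) > 3:
                rec["fastq2"] = parts[3]
            samples.append(rec)
    return samples


def read_sex_labels(path) -> dict:
    """manifest (TSV or JSON) -> {sample_id: sex}."""
    out = {}
    for rec in read_manifest(path):
        sex = rec["sex"].lower()
        if sex not in ("male", "female"):
            raise ValueError(f"unknown sex label {rec['sex']!r} for sample {rec['sample_id']}")
        out[rec["sample_id"]] = sex
    return out


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=xykit
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(path, chrom, pos, ref, alt, dosages, samples, chrom_lengths=None) -> None:
    """Biallelic diploid VCFv4.2 from a sites x samples dosage matrix (-1 = missing)."""
    contigs = ""
    if chrom_lengths:
        contigs = "".join(f"##contig=<ID={c},length={l}>\n" for c, l in chrom_lengths.items())
    dosages = np.asarray(dosages)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contigs, samples="\t".join(samples)))
        for i in range(dosages.shape[0]):
            gts = "\t".join(_GT[int(d)] for d in dosages[i])
            fh.write(f"{chrom}\t{int(pos[i])}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_gff3_genes(path):
    """Yield (gene_id, chrom, start0, end) for type=gene rows, 0-based half-open."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: GFF3 line does not have 9 columns")
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"gene_at_{parts[0]}:{start}")
            genes.append((gene_id, parts[0], start - 1, end))
    return genes


def write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
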