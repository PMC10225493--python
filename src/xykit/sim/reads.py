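"""Whole-genome shotgun read simulator for the XY genome pair.

Males draw reads from one X plus one Y haplotype, females from two X copies.
Read names carry the truth channel: ``{sample}|{hap}|{chrom}|{start}|{strand}|{i}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .._util import bernoulli_positions, mutate_sites, revcomp_bytes, rng_stream, seq_to_array, window_view
from ..io import write_manifest
from ..readset import ReadSet
from .genome import GenomePair


@dataclass
class ReadSimParams:
    n_males: int = 4
    n_females: int = 4
    coverage: float = 10.0
    read_length: int = 100
    error_rate: float = 0.0
    paired: bool = False
    insert_size: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("sample counts must be >= 0")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.paired and self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length for paired reads")


def _draw_haplotype_reads(
    rng: np.random.Generator,
    sample: str,
    hap_name: str,
    chroms: Dict[str, str],
    coverage: float,
    read_length: int,
    error_rate: float,
) -> Tuple[List[tuple], np.ndarray]:
    ids: List[tuple] = []
    blocks: List[np.ndarray] = []
    for chrom, seq in chroms.items():
        if len(seq) < read_length:
            raise ValueError(f"read_length {read_length} exceeds chromosome {chrom} length {len(seq)}")
        n = rng.poisson(coverage * len(seq) / read_length)
        if n == 0:
            continue
        arr = seq_to_array(seq)
        starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        strands = rng.random(n) < 0.5
        reads = window_view(arr, read_length)[starts]
        if strands.any():
            reads[strands] = revcomp_bytes(reads[strands])
        if error_rate > 0:
            flat = reads.reshape(-1)
            mutate_sites(rng, flat, bernoulli_positions(rng, flat.size, error_rate))
        blocks.append(reads)
        ids.append((f"{sample}|{hap_name}|{chrom}", starts, strands))
    if not blocks:
        return ids, np.zeros((0, read_length), dtype=np.uint8)
    return ids, np.concatenate(blocks, axis=0)


def _draw_haplotype_pairs(
    rng: np.random.Generator,
    sample: str,
    hap_name: str,
    chroms: Dict[str, str],
    coverage: float,
    read_length: int,
    insert_size: int,
    error_rate: float,
) -> Tuple[List[tuple], np.ndarray]:
    """Paired-end mode: R1 forward from fragment start, R2 reverse from fragment end."""
    ids: List[tuple] = []
    blocks: List[np.ndarray] = []
    for chrom, seq in chroms.items():
        if len(seq) < insert_size:
            raise ValueError(f"insert_size {insert_size} exceeds chromosome {chrom} length {len(seq)}")
        n_frag = rng.poisson(coverage * len(seq) / (2 * read_length))
        if n_frag == 0:
            continue
        arr = seq_to_array(seq)
        starts = rng.integers(0, len(seq) - insert_size + 1, size=n_frag)
        view = window_view(arr, read_length)
        r1 = view[starts]
        r2_start = starts + insert_size - read_length
        r2 = revcomp_bytes(view[r2_start])
        reads = np.concatenate([r1, r2], axis=0)
        if error_rate > 0:
            flat = reads.reshape(-1)
            mutate_sites(rng, flat, bernoulli_positions(rng, flat.size, error_rate))
        blocks.append(reads)
        ids.append((f"{sample}|{hap_name}|{chrom}", starts, np.zeros(n_frag, dtype=bool)))
        ids.append((f"{sample}|{hap_name}|{chrom}", r2_start, np.ones(n_frag, dtype=bool)))
    if not blocks:
        return ids, np.zeros((0, read_length), dtype=np.uint8)
    return ids, np.concatenate(blocks, axis=0)


def simulate_reads(genomes: GenomePair, params: ReadSimParams) -> Dict[str, ReadSet]:
    """Return {sample_id: ReadSet}; sample ids are M1..Mn then F1..Fn.

    Per-sample read count is Poisson with mean coverage x genome length /
    read length, split evenly between the two haplotypes.
    """
    params.validate()
    out: Dict[str, ReadSet] = {}
    male_haps = {"X": genomes.female_assembly, "Y": genomes.male_assembly}
    female_haps = {"X1": genomes.female_assembly, "X2": genomes.female_assembly}
    for sex, n, haps in (("M", params.n_males, male_haps), ("F", params.n_females, female_haps)):
        for j in range(1, n + 1):
            sample = f"{sex}{j}"
            rng = rng_stream(params.seed, f"reads-{sample}")
            segments: List[tuple] = []
            mats: List[np.ndarray] = []
            for hap_name, chroms in haps.items():
                if params.paired:
                    ids, mat = _draw_haplotype_pairs(
                        rng, sample, hap_name, chroms, params.coverage / 2.0,
                        params.read_length, params.insert_size, params.error_rate,
                    )
                    segments.extend(ids)
                    mats.append(mat)
                else:
                    ids, mat = _draw_haplotype_reads(
                        rng, sample, hap_name, chroms, params.coverage / 2.0,
                        params.read_length, params.error_rate,
                    )
                    segments.extend(ids)
                    mats.append(mat)
            mat = np.concatenate(mats, axis=0) if mats else np.zeros((0, params.read_length), np.uint8)
            out[sample] = ReadSet(_segment_id_maker(segments), mat)
    return out


def _segment_id_maker(segments: List[tuple]):
    """Lazy truth-channel names: ``prefix|start|strand|i`` per segment.

    segments: list of (prefix, starts array, strands bool array) in row order.
    """
    offsets = np.cumsum([0] + [len(s[1]) for s in segments])

    def maker(i: int) -> str:
        seg = int(np.searchsorted(offsets, i, side="right")) - 1
        prefix, starts, strands = segments[seg]
        local = i - offsets[seg]
        strand = "-" if strands[local] else "+"
        return f"{prefix}|{starts[local]}|{strand}|{local}"

    return maker


def write_read_sets(read_sets: Dict[str, ReadSet], out_dir, gzip_output: bool = True) -> list:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_output else ".fastq"
    manifest = []
    for sample, rs in read_sets.items():
        path = out / f"{sample}{ext}"
        rs.write_fastq(path)
        sex = "male" if sample.startswith("M") else "female"
        manifest.append({"sample_id": sample, "sex": sex, "fastq1": str(path)})
    write_manifest(out / "manifest.json", manifest)
    return manifest
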