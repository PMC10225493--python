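"""Simulate an XY dioecious genome pair with a diverged SDR and a Y-only insertion."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .._util import array_to_seq, mutate_sites, random_sequence, rng_stream
from ..io import write_fasta
from .truth import TruthSet


@dataclass
class SimGenomeParams:
    chrom_lengths: Tuple[int, ...] = (5_000_000, 2_000_000, 2_000_000)
    sex_chrom_index: int = 0
    sdr_interval: Tuple[int, int] = (3_000_000, 3_400_000)  # 0-based half-open, X coords
    msr_length: int = 60_000
    sdr_divergence: float = 0.02
    background_polymorphism: float = 0.0
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def validate(self) -> None:
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chrom_lengths must be positive")
        if not 0 <= self.sex_chrom_index < len(self.chrom_lengths):
            raise ValueError("sex_chrom_index out of range")
        s, e = self.sdr_interval
        if not (0 <= s < e <= self.chrom_lengths[self.sex_chrom_index]):
            raise ValueError("sdr_interval outside the sex chromosome")
        if self.msr_length < 0:
            raise ValueError("msr_length must be >= 0")
        for rate in (self.sdr_divergence, self.background_polymorphism):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GenomePair:
    """One X and one Y haplotype per chromosome (autosomes shared verbatim)."""

    x: Dict[str, str]
    y: Dict[str, str]
    sex_chrom: str
    chrom_names: Tuple[str, ...]

    @property
    def male_assembly(self) -> Dict[str, str]:
        """Y-bearing assembly: Y haplotype on the sex chromosome, X elsewhere."""
        return {c: (self.y[c] if c == self.sex_chrom else self.x[c]) for c in self.chrom_names}

    @property
    def female_assembly(self) -> Dict[str, str]:
        return dict(self.x)

    def chrom_lengths(self, assembly: str = "male") -> Dict[str, int]:
        src = self.male_assembly if assembly == "male" else self.female_assembly
        return {c: len(s) for c, s in src.items()}

    def write(self, out_dir, prefix: str = "sim") -> dict:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        male = out / f"{prefix}_male.fasta"
        female = out / f"{prefix}_female.fasta"
        write_fasta(male, self.male_assembly.items())
        write_fasta(female, self.female_assembly.items())
        return {"male_fasta": str(male), "female_fasta": str(female)}


def simulate_xy_genome(params: SimGenomeParams) -> Tuple[GenomePair, TruthSet]:
    """Build X/Y haplotypes that differ only inside the SDR.

    Inside the SDR the Y copy carries substitutions at ``sdr_divergence`` per
    site plus one Y-only insertion of ``msr_length``; ``background_polymorphism``
    optionally adds X/Y heterozygous sites outside the SDR (default off, which
    makes X and Y byte-identical there).  Truth coordinates are reported on the
    Y-bearing (male) assembly.
    """
    params.validate()
    rng = rng_stream(params.seed, "xy-genome")
    names = tuple(f"chr{i + 1}" for i in range(len(params.chrom_lengths)))
    sex_chrom = names[params.sex_chrom_index]

    x: Dict[str, str] = {}
    y: Dict[str, str] = {}
    sdr_s, sdr_e = params.sdr_interval
    for name, length in zip(names, params.chrom_lengths):
        arr = random_sequence(rng, length, params.base_composition)
        x[name] = array_to_seq(arr)
        if name != sex_chrom:
            y[name] = x[name]
            continue
        yarr = arr.copy()
        # divergent substitutions inside the SDR
        if params.sdr_divergence > 0:
            hits = np.flatnonzero(rng.random(sdr_e - sdr_s) < params.sdr_divergence) + sdr_s
            mutate_sites(rng, yarr, hits)
        # background X/Y polymorphism outside the SDR (off by default)
        if params.background_polymorphism > 0:
            outside = np.concatenate(
                [
                    np.flatnonzero(rng.random(sdr_s) < params.background_polymorphism),
                    sdr_e + np.flatnonzero(rng.random(length - sdr_e) < params.background_polymorphism),
                ]
            )
            mutate_sites(rng, yarr, outside)
        # Y-only insertion at a position inside the SDR
        if params.msr_length > 0:
            ins_at = int(rng.integers(sdr_s, sdr_e + 1))
            insert = random_sequence(rng, params.msr_length, params.base_composition)
            yarr = np.concatenate([yarr[:ins_at], insert, yarr[ins_at:]])
        else:
            ins_at = sdr_s
        y[name] = array_to_seq(yarr)

    truth = TruthSet(
        sdr=(sex_chrom, sdr_s, sdr_e + params.msr_length),
        msr=(sex_chrom, ins_at, ins_at + params.msr_length) if params.msr_length > 0 else None,
    )
    pair = GenomePair(x=x, y=y, sex_chrom=sex_chrom, chrom_names=names)
    return pair, truth
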