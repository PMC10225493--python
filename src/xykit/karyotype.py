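"""Synteny-block bookkeeping: EFR detection, fusion/fission parsimony counts,
and repeat-class content of fusion regions.

Counting rules (parsimony lower bounds):
  fusions  = sum over target chromosomes of (maximal runs of constant
             ancestral id - 1)
  fissions = sum over ancestral chromosomes of (distinct target chromosomes
             carrying >= 1 of its blocks - 1)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from ._util import covered_length, merge_intervals
from .io import read_bed

_COLS = ["target_chrom", "start", "end", "ancestral_chrom", "orientation"]


@dataclass
class BlockTable:
    blocks: pd.DataFrame  # sorted per target chromosome
    min_block_length: int = 0

    def per_chrom(self) -> Dict[str, pd.DataFrame]:
        return {c: g.reset_index(drop=True) for c, g in self.blocks.groupby("target_chrom", sort=True)}

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class EFR:
    target_chrom: str
    start: int
    end: int
    junction_type: str  # "ancestry-switch" | "same-ancestry"
    left_block: int
    right_block: int

    @property
    def zero_length(self) -> bool:
        return self.end == self.start


@dataclass
class EventCounts:
    n_fusion: int
    n_fission: int


def load_blocks(table, min_block_length: int = 1_200_000) -> BlockTable:
    """Load a 5-column block table (TSV path or DataFrame), filter and sort.

    Blocks shorter than ``min_block_length`` are dropped; retained blocks must
    not overlap within a target chromosome.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        if list(df.columns) != _COLS:
            if df.shape[1] != 5:
                raise ValueError("block table needs 5 columns")
            df.columns = _COLS
    else:
        df = _read_block_tsv(table)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"block row {bad}: end must exceed start")
    if not df["orientation"].isin(["+", "-"]).all():
        raise ValueError("orientation must be '+' or '-'")
    df = df[(df["end"] - df["start"]) >= min_block_length]
    df = df.sort_values(["target_chrom", "start", "end"]).reset_index(drop=True)
    for chrom, g in df.groupby("target_chrom"):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping retained blocks on {chrom}")
    return BlockTable(blocks=df, min_block_length=min_block_length)


def _read_block_tsv(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected 5 tab-separated columns")
            if ln == 1 and not _is_int(parts[1]):
                continue  # header row
            if not (_is_int(parts[1]) and _is_int(parts[2])):
                raise ValueError(f"{path}:{ln}: start/end must be integers")
            rows.append(parts[:5])
    return pd.DataFrame(rows, columns=_COLS)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def detect_efrs(blocks: BlockTable) -> List[EFR]:
    """One EFR per adjacent retained-block pair per target chromosome."""
    efrs: List[EFR] = []
    for chrom, g in blocks.per_chrom().items():
        for i in range(len(g) - 1):
            left, right = g.iloc[i], g.iloc[i + 1]
            jtype = (
                "ancestry-switch"
                if left["ancestral_chrom"] != right["ancestral_chrom"]
                else "same-ancestry"
            )
            efrs.append(
                EFR(
                    target_chrom=chrom,
                    start=int(left["end"]),
                    end=int(right["start"]),
                    junction_type=jtype,
                    left_block=int(left.name),
                    right_block=int(right.name),
                )
            )
    return efrs


def count_events(blocks: BlockTable) -> EventCounts:
    n_fusion = 0
    for _, g in blocks.per_chrom().items():
        anc = g["ancestral_chrom"].to_numpy()
        if anc.size == 0:
            continue
        runs = 1 + int(np.sum(anc[1:] != anc[:-1]))
        n_fusion += runs - 1
    spread = blocks.blocks.groupby("ancestral_chrom")["target_chrom"].nunique()
    n_fission = int((spread - 1).sum())
    return EventCounts(n_fusion=n_fusion, n_fission=n_fission)


@dataclass
class RepeatEnrichment:
    per_class: pd.DataFrame  # columns: repeat_class, efr_fraction, genome_fraction, ratio
    efr_bases: int
    genome_bases: int


def repeat_enrichment(efrs: List[EFR], repeats, chrom_lengths: Dict[str, int]) -> RepeatEnrichment:
    """Covered-base fractions per repeat class, inside EFRs vs whole genome.

    ``repeats``: BED path or iterable of (chrom, start, end, repeat_class).
    Coverage is computed on merged intervals so overlapping annotations of one
    class are not double-counted.
    """
    if isinstance(repeats, (str, Path)):
        repeats = read_bed(repeats)
    rows = []
    for rec in repeats:
        if len(rec) < 4:
            raise ValueError("repeat BED needs a 4th (class) column")
        chrom, s, e, cls = rec[0], int(rec[1]), int(rec[2]), rec[3]
        if chrom not in chrom_lengths:
            raise ValueError(f"repeat interval on unknown chromosome {chrom}")
        if s < 0 or e > chrom_lengths[chrom]:
            raise ValueError(f"repeat interval {chrom}:{s}-{e} beyond chromosome end")
        rows.append((chrom, s, e, cls))

    efr_by_chrom: Dict[str, list] = {}
    for efr in efrs:
        efr_by_chrom.setdefault(efr.target_chrom, []).append((efr.start, efr.end))
    efr_by_chrom = {c: merge_intervals(iv) for c, iv in efr_by_chrom.items()}
    efr_bases = sum(covered_length(iv) for iv in efr_by_chrom.values())
    genome_bases = sum(chrom_lengths.values())

    classes = sorted({r[3] for r in rows})
    out = []
    for cls in classes:
        by_chrom: Dict[str, list] = {}
        for chrom, s, e, c in rows:
            if c == cls:
                by_chrom.setdefault(chrom, []).append((s, e))
        genome_cov = sum(covered_length(iv) for iv in by_chrom.values())
        efr_cov = 0
        for chrom, ivs in by_chrom.items():
            for ms, me in merge_intervals(ivs):
                for es, ee in efr_by_chrom.get(chrom, []):
                    lo, hi = max(ms, es), min(me, ee)
                    if hi > lo:
                        efr_cov += hi - lo
        efr_frac = efr_cov / efr_bases if efr_bases else 0.0
        genome_frac = genome_cov / genome_bases if genome_bases else 0.0
        ratio = efr_frac / genome_frac if genome_frac > 0 else float("nan")
        out.append((cls, efr_frac, genome_frac, ratio))
    df = pd.DataFrame(out, columns=["repeat_class", "efr_fraction", "genome_fraction", "ratio"])
    return RepeatEnrichment(per_class=df, efr_bases=efr_bases, genome_bases=genome_bases)
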