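"""Derive a karyotype from an ancestral one by known fusion/fission events.

Events are guaranteed non-cancelling: a fusion only joins chromosomes whose
ancestral-id sets are disjoint (so parsimony run counting stays exact) and a
fission always splits strictly inside one ancestral segment, never at a
junction created by an earlier fusion.
"""

from __future__ import annotations

from typing import List, Tuple

import pandas as pd

from .._util import rng_stream
from ..karyotype import BlockTable, load_blocks
from .truth import TruthSet

# one block = (ancestral_id, anc_start, anc_end, orientation)
_Chrom = List[Tuple[str, int, int, str]]


def simulate_karyotype(
    n_ancestral: int,
    n_fusions: int,
    n_fissions: int,
    seed: int = 0,
    segment_length_range: Tuple[int, int] = (2_000_000, 6_000_000),
    gap_range: Tuple[int, int] = (20_000, 150_000),
    min_fission_piece: int = 200_000,
) -> Tuple[BlockTable, TruthSet]:
    if n_ancestral < 1 or n_fusions < 0 or n_fissions < 0:
        raise ValueError("counts must be non-negative and n_ancestral >= 1")
    if n_ancestral - n_fusions < 1:
        raise ValueError("cannot fuse below one chromosome")
    rng = rng_stream(seed, "karyotype")

    chroms: List[_Chrom] = []
    for i in range(n_ancestral):
        length = int(rng.integers(segment_length_range[0], segment_length_range[1] + 1))
        chroms.append([(f"A{i + 1}", 0, length, "+")])

    events = ["fusion"] * n_fusions + ["fission"] * n_fissions
    rng.shuffle(events)
    applied_fu = applied_fi = 0
    for ev in events:
        if ev == "fusion":
            # candidate pairs with disjoint ancestral-id sets
            sets = [frozenset(b[0] for b in c) for c in chroms]
            pairs = [
                (i, j)
                for i in range(len(chroms))
                for j in range(i + 1, len(chroms))
                if not (sets[i] & sets[j])
            ]
            if not pairs:
                raise ValueError("no non-cancelling fusion possible")
            i, j = pairs[rng.integers(0, len(pairs))]
            left, right = chroms[i], chroms[j]
            if rng.random() < 0.5:
                left = _flip(left)
            if rng.random() < 0.5:
                right = _flip(right)
            merged = left + right
            chroms = [c for k, c in enumerate(chroms) if k not in (i, j)] + [merged]
            applied_fu += 1
        else:
            # split strictly inside an ancestral segment
            candidates = [
                (ci, bi)
                for ci, c in enumerate(chroms)
                for bi, b in enumerate(c)
                if b[2] - b[1] >= 2 * min_fission_piece
            ]
            if not candidates:
                raise ValueError("no block long enough for a non-cancelling fission")
            ci, bi = candidates[rng.integers(0, len(candidates))]
            anc, s, e, orient = chroms[ci][bi]
            cut = int(rng.integers(s + min_fission_piece, e - min_fission_piece + 1))
            first, second = (anc, s, cut, orient), (anc, cut, e, orient)
            if orient == "-":
                first, second = (anc, cut, e, orient), (anc, s, cut, orient)
            part1 = chroms[ci][:bi] + [first]
            part2 = [second] + chroms[ci][bi + 1 :]
            chroms = [c for k, c in enumerate(chroms) if k != ci] + [part1, part2]
            applied_fi += 1

    rows = []
    efrs = []
    for ti, blocks in enumerate(chroms, start=1):
        name = f"D{ti}"
        pos = 0
        prev_end = None
        prev_anc = None
        for anc, s, e, orient in blocks:
            if prev_end is not None:
                gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
                pos = prev_end + gap
                jtype = "ancestry-switch" if anc != prev_anc else "same-ancestry"
                efrs.append((name, prev_end, pos, jtype))
            length = e - s
            rows.append((name, pos, pos + length, anc, orient))
            prev_end = pos + length
            prev_anc = anc
    table = pd.DataFrame(rows, columns=["target_chrom", "start", "end", "ancestral_chrom", "orientation"])
    truth = TruthSet(n_fusions=applied_fu, n_fissions=applied_fi, efrs=efrs)
    return load_blocks(table, min_block_length=0), truth


def _flip(chrom: _Chrom) -> _Chrom:
    return [(anc, s, e, "-" if o == "+" else "+") for anc, s, e, o in reversed(chrom)]
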