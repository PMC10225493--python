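"""Placement of labeled reads, windowed depth tracks and SDR calling.

The internal placer is deterministic and aligner-free: a read is placed
where its first N-free seed substring matches the reference uniquely (both
orientations considered) and the full read aligns with at most
``max_mismatch`` substitutions.  External mode consumes a coordinate-sorted
SAM/BAM instead.  Placements are deduplicated on (chrom, start, strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._util import CODE4, revcomp_bytes, seq_to_array
from .readset import ReadSet, as_readset

DEFAULT_SEED_LENGTH = 31  # fits exact 2-bit packing in 64 bits


@dataclass
class Placement:
    read_id: str
    chrom: str
    start: int  # 0-based
    strand: str  # "+" | "-"
    unique: bool = True


# ---------------------------------------------------------------- reference index


class ReferenceIndex:
    """Exact-match seed index over the forward strand of a reference."""

    def __init__(self, reference: Dict[str, str], seed_length: int = DEFAULT_SEED_LENGTH):
        if seed_length > 32:
            raise ValueError("seed_length must be <= 32 for exact packing")
        self.seed_length = seed_length
        self.chrom_names = list(reference)
        self.chrom_lengths = {c: len(s) for c, s in reference.items()}
        self._arrs = {c: seq_to_array(s) for c, s in reference.items()}
        codes_all, pos_all, cid_all = [], [], []
        for ci, chrom in enumerate(self.chrom_names):
            arr = self._arrs[chrom]
            if arr.size < seed_length:
                continue
            codes = _pack_windows(arr, seed_length)
            valid = codes >= 0
            codes_all.append(codes[valid])
            pos_all.append(np.flatnonzero(valid))
            cid_all.append(np.full(int(valid.sum()), ci, dtype=np.int32))
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = np.concatenate(pos_all)[order]
            self._cid = np.concatenate(cid_all)[order]
        else:
            self._codes = np.zeros(0, dtype=np.int64)
            self._pos = np.zeros(0, dtype=np.int64)
            self._cid = np.zeros(0, dtype=np.int32)

    def lookup(self, codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per query code: (hit count, chrom id of first hit, position of first hit)."""
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        n = hi - lo
        first = np.minimum(lo, max(self._codes.size - 1, 0))
        return n, self._cid[first] if self._cid.size else np.zeros_like(codes, dtype=np.int32), (
            self._pos[first] if self._pos.size else np.zeros_like(codes)
        )

    @classmethod
    def from_fasta(cls, path, seed_length: int = DEFAULT_SEED_LENGTH) -> "ReferenceIndex":
        from .io import read_fasta

        return cls(read_fasta(path), seed_length=seed_length)


def _pack_windows(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack every k-window; -1 where the window contains a non-ACGT byte."""
    try:
        from ._kernels import HAVE_NUMBA, pack_reference_windows

        if HAVE_NUMBA:
            return pack_reference_windows(arr, k)
    except ImportError:
        pass
    codes = CODE4[arr].astype(np.int64)
    bad = codes == 255
    m = arr.size - k + 1
    out = np.zeros(m, dtype=np.int64)
    invalid = np.zeros(m, dtype=bool)
    for j in range(k):
        out = out * 4 + np.where(bad[j : j + m], 0, codes[j : j + m])
        invalid |= bad[j : j + m]
    out[invalid] = -1
    return out


# ---------------------------------------------------------------- placement


def place_reads(
    reads,
    reference,
    mode: str = "internal",
    max_mismatch: int = 2,
    seed_length: int = DEFAULT_SEED_LENGTH,
    min_mapq: int = 20,
    sam_path=None,
    dedup: bool = True,
) -> List[Placement]:
    if mode == "external":
        return _place_external(sam_path, min_mapq=min_mapq, dedup=dedup)
    if mode != "internal":
        raise ValueError(f"unknown placement mode {mode!r}")
    index = reference if isinstance(reference, ReferenceIndex) else (
        ReferenceIndex.from_fasta(reference, seed_length)
        if isinstance(reference, (str, Path))
        else ReferenceIndex(reference, seed_length)
    )
    rs = as_readset(reads)
    if len(rs) == 0:
        return []
    placements = _place_internal(rs, index, max_mismatch)
    if dedup:
        placements = deduplicate(placements)
    return placements


def _first_seed_codes(mat: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """First N-free k-window per read: (codes, offsets); code -1 if none."""
    n, L = mat.shape
    codes = np.full(n, -1, dtype=np.int64)
    offs = np.zeros(n, dtype=np.int64)
    remaining = np.arange(n)
    col = 0
    while remaining.size and col + k <= L:
        c = _pack_windows_rows(mat[remaining][:, col : col + k])
        good = c >= 0
        codes[remaining[good]] = c[good]
        offs[remaining[good]] = col
        remaining = remaining[~good]
        col += 1
    return codes, offs


def _pack_windows_rows(win: np.ndarray) -> np.ndarray:
    codes = CODE4[win].astype(np.int64)
    bad = (codes == 255).any(axis=1)
    out = np.zeros(win.shape[0], dtype=np.int64)
    for j in range(win.shape[1]):
        out = out * 4 + np.where(codes[:, j] == 255, 0, codes[:, j])
    out[bad] = -1
    return out


def _place_internal(rs: ReadSet, index: ReferenceIndex, max_mismatch: int) -> List[Placement]:
    if not rs.uniform_length:
        placements: List[Placement] = []
        for i in range(len(rs)):
            one = ReadSet.from_strings([rs.sequence(i)], [rs.ids[i]])
            placements.extend(_place_internal(one, index, max_mismatch))
        return placements
    mat = rs.matrix
    L = mat.shape[1]
    k = index.seed_length
    if L < k:
        raise ValueError(f"reads shorter than seed length {k}")
    results: List[Placement] = []
    rc = revcomp_bytes(mat)
    hits_per_read = np.zeros(len(rs), dtype=np.int64)
    candidates: List[Tuple[int, int, int, str, int]] = []  # (read, cid, start, strand, offset)
    for strand, m in (("+", mat), ("-", rc)):
        codes, offs = _first_seed_codes(m, k)
        n_hits, cid, pos = index.lookup(np.where(codes >= 0, codes, 0))
        n_hits = np.where(codes >= 0, n_hits, 0)
        hits_per_read += n_hits
        sel = np.flatnonzero(n_hits == 1)
        for i in sel:
            candidates.append((int(i), int(cid[i]), int(pos[i] - offs[i]), strand, int(offs[i])))
    for i, ci, start, strand, off in candidates:
        if hits_per_read[i] != 1:  # seed hit in both orientations or multiple loci
            continue
        chrom = index.chrom_names[ci]
        ref = index._arrs[chrom]
        if start < 0 or start + L > ref.size:
            continue
        read = mat[i] if strand == "+" else revcomp_bytes(mat[i : i + 1])[0]
        if int((ref[start : start + L] != read).sum()) <= max_mismatch:
            results.append(Placement(rs.ids[i], chrom, start, strand))
    return results


def _place_external(sam_path, min_mapq: int = 20, dedup: bool = True) -> List[Placement]:
    import pysam

    if sam_path is None:
        raise ValueError("external mode needs sam_path")
    placements: List[Placement] = []
    with pysam.AlignmentFile(str(sam_path)) as fh:
        if fh.header.get("HD", {}).get("SO") not in ("coordinate",):
            raise ValueError("external mode requires a coordinate-sorted SAM/BAM")
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            placements.append(
                Placement(rec.query_name, rec.reference_name, rec.reference_start, "-" if rec.is_reverse else "+")
            )
    return deduplicate(placements) if dedup else placements


def deduplicate(placements: Sequence[Placement]) -> List[Placement]:
    seen = set()
    out = []
    for p in placements:
        key = (p.chrom, p.start, p.strand)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


# ---------------------------------------------------------------- window tracks


@dataclass
class WindowTrack:
    chrom_lengths: Dict[str, int]
    window: int
    counts: Dict[str, np.ndarray]  # raw per-window placement counts
    norm: Dict[str, np.ndarray]  # counts per million placed reads
    total_placements: int

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.window == other.window
            and self.chrom_lengths == other.chrom_lengths
        )

    def window_bounds(self, chrom: str) -> np.ndarray:
        n = self.counts[chrom].size
        starts = np.arange(n) * self.window
        ends = np.minimum(starts + self.window, self.chrom_lengths[chrom])
        return np.stack([starts, ends], axis=1)

    def partial_final_window(self, chrom: str) -> bool:
        return self.chrom_lengths[chrom] % self.window != 0

    def all_values(self, normalized: bool = True) -> np.ndarray:
        src = self.norm if normalized else self.counts
        return np.concatenate([src[c] for c in sorted(src)])

    def to_bedgraph(self, path, normalized: bool = True) -> None:
        src = self.norm if normalized else self.counts
        with open(path, "w") as fh:
            for chrom in self.counts:
                for (s, e), v in zip(self.window_bounds(chrom), src[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def window_depth(
    placements: Sequence[Placement],
    chrom_lengths: Dict[str, int],
    window: int,
    normalize: bool = True,
) -> WindowTrack:
    """Bin placements into fixed windows by start coordinate."""
    if window <= 0:
        raise ValueError("window must be positive")
    counts = {
        c: np.zeros((l + window - 1) // window, dtype=np.int64) for c, l in chrom_lengths.items()
    }
    for p in placements:
        if p.chrom not in counts:
            raise ValueError(f"placement on unknown chromosome {p.chrom}")
        if not 0 <= p.start < chrom_lengths[p.chrom]:
            raise ValueError(f"placement beyond chromosome end: {p.chrom}:{p.start}")
        counts[p.chrom][p.start // window] += 1
    total = int(sum(int(v.sum()) for v in counts.values()))
    scale = 1e6 / total if (normalize and total > 0) else 0.0
    norm = {c: v * scale for c, v in counts.items()}
    return WindowTrack(dict(chrom_lengths), window, counts, norm, total)


# ---------------------------------------------------------------- SDR calling


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    total_reads: int
    mean_norm_depth: float
    rank: int = 0


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def call_sdr(
    male_track: WindowTrack,
    female_track: WindowTrack,
    z: float = 4.0,
    merge_gap: int = 2,
    min_windows: int = 2,
    max_female_fraction: float = 0.1,
) -> List[CandidateRegion]:
    """Call candidate SDR intervals from per-sex specific-read depth tracks.

    Seed windows: male normalized depth strictly above median + z*MAD of the
    whole male track, without a co-localized female signal.  A window is
    female-vetoed only when its female depth is an outlier on the female
    track (above median + z*MAD of normalized values) AND non-negligible
    next to the male signal (raw female count > max_female_fraction x raw
    male count); the second clause keeps a near-empty female track - where
    median and MAD are both zero and a single stray read would otherwise
    veto a window - from erasing true hemizygous windows.
    Seeds separated by <= merge_gap windows merge; regions with fewer than
    min_windows seed windows are dropped; ranking is by total raw reads.
    """
    if not male_track.same_grid(female_track):
        raise ValueError("male and female tracks are on different grids")
    mvals = male_track.all_values()
    fvals = female_track.all_values()
    m_thresh = float(np.median(mvals)) + z * _mad(mvals)
    f_thresh = float(np.median(fvals)) + z * _mad(fvals)

    regions: List[CandidateRegion] = []
    for chrom in sorted(male_track.counts):
        m = male_track.norm[chrom]
        f = female_track.norm[chrom]
        f_veto = (f > f_thresh) & (
            female_track.counts[chrom] > max_female_fraction * male_track.counts[chrom]
        )
        seeds = np.flatnonzero((m > m_thresh) & ~f_veto)
        if seeds.size == 0:
            continue
        clusters: List[List[int]] = [[int(seeds[0])]]
        for w in seeds[1:]:
            if w - clusters[-1][-1] <= merge_gap + 1:
                clusters[-1].append(int(w))
            else:
                clusters.append([int(w)])
        bounds = male_track.window_bounds(chrom)
        for cl in clusters:
            if len(cl) < min_windows:
                continue
            lo, hi = cl[0], cl[-1]
            total = int(male_track.counts[chrom][lo : hi + 1].sum())
            regions.append(
                CandidateRegion(
                    chrom=chrom,
                    start=int(bounds[lo, 0]),
                    end=int(bounds[hi, 1]),
                    n_windows=len(cl),
                    total_reads=total,
                    mean_norm_depth=float(m[lo : hi + 1].mean()),
                )
            )
    regions.sort(key=lambda r: (-r.total_reads, r.chrom, r.start))
    for rank, r in enumerate(regions, 1):
        r.rank = rank
    return regions


def coverage_ratio(
    male_track: WindowTrack, female_track: WindowTrack, pseudocount: float = 1.0
) -> Dict[str, np.ndarray]:
    """Per-window log2((male + c) / (female + c)) on normalized values."""
    if not male_track.same_grid(female_track):
        raise ValueError("tracks are on different grids")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return {
        c: np.log2((male_track.norm[c] + pseudocount) / (female_track.norm[c] + pseudocount))
        for c in male_track.norm
    }


# ---------------------------------------------------------------- variant density


@dataclass
class VariantDensityTrack:
    chrom_lengths: Dict[str, int]
    window: int
    het_snp: Dict[str, Dict[str, np.ndarray]]  # sex -> chrom -> mean per-sample het count
    het_indel: Dict[str, Dict[str, np.ndarray]]
    male_specific_snp: Dict[str, np.ndarray]
    male_specific_indel: Dict[str, np.ndarray]


def sex_variant_density(
    vcf_path,
    sex_labels: Dict[str, str],
    window: int,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> VariantDensityTrack:
    """Per-window heterozygous SNP/indel density per sex plus male-specific
    variant density (non-reference allele in every male, absent in every
    female)."""
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    missing = set(sex_labels) - set(samples)
    if missing:
        raise ValueError(f"samples in labels missing from VCF: {sorted(missing)}")
    males = [s for s in samples if sex_labels.get(s) == "male"]
    females = [s for s in samples if sex_labels.get(s) == "female"]
    if not males or not females:
        raise ValueError("need at least one sample per sex")
    if chrom_lengths is None:
        chrom_lengths = {
            name: ctg.length for name, ctg in vf.header.contigs.items() if ctg.length
        }
        if not chrom_lengths:
            raise ValueError("no contig lengths in VCF header; pass chrom_lengths")

    def _zeros():
        return {c: np.zeros((l + window - 1) // window) for c, l in chrom_lengths.items()}

    het_snp = {"male": _zeros(), "female": _zeros()}
    het_indel = {"male": _zeros(), "female": _zeros()}
    ms_snp = _zeros()
    ms_indel = _zeros()

    for rec in vf:
        if rec.chrom not in chrom_lengths:
            continue
        w = (rec.pos - 1) // window
        alts = rec.alts or ()
        is_snp = len(rec.ref) == 1 and all(len(a) == 1 for a in alts) and len(alts) >= 1
        gts = {s: rec.samples[s].get("GT") for s in samples}

        def _het(gt):
            return gt is not None and None not in gt and len(set(gt)) > 1

        def _carries_alt(gt):
            return gt is not None and None not in gt and any(a != 0 for a in gt)

        for sex, members in (("male", males), ("female", females)):
            n_het = sum(1 for s in members if _het(gts[s]))
            target = het_snp if is_snp else het_indel
            target[sex][rec.chrom][w] += n_het / len(members)
        if all(_carries_alt(gts[s]) for s in males) and not any(_carries_alt(gts[s]) for s in females):
            (ms_snp if is_snp else ms_indel)[rec.chrom][w] += 1
    return VariantDensityTrack(chrom_lengths, window, het_snp, het_indel, ms_snp, ms_indel)
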