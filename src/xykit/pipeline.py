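"""End-to-end SDR discovery pipeline on simulated cohorts.

Chains: simulate genome -> simulate reads -> per-sample k-mer catalogs ->
MSK/FSK classification -> read labeling -> placement on the male assembly ->
windowed depth -> SDR calling; returns the calls next to the simulator truth
so parameter recovery can be scored.

Two engines produce identical partitions on the same input:

* ``exact``  - the public string-keyed API (SampleKmerCounts et al.).
* ``hashed`` - 64-bit fingerprints of the k-mers carry the whole
  classification; collision probability is ~1e-7 for desk-scale catalogs.
  Used for large runs where string sorting dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._util import encode_kmers_int64
from .kmers import (
    KmerParams,
    SampleKmerCounts,
    _count_windows,
    classify_sex_kmers,
    collect_kmer_occurrences,
    label_reads,
    merge_samples,
)
from .readset import ReadSet
from .sdr import CandidateRegion, ReferenceIndex, call_sdr, place_reads, window_depth
from .sim import ReadSimParams, SimGenomeParams, TruthSet, simulate_reads, simulate_xy_genome


@dataclass
class SdrRunResult:
    truth: TruthSet
    regions: List[CandidateRegion]
    n_msk: int
    n_fsk: int
    label_sizes: Dict[str, Dict[str, int]]
    male_track: object
    female_track: object

    def jaccard_vs_truth(self) -> float:
        """Jaccard of the best called region against the truth SDR (male coords)."""
        if not self.regions or self.truth.sdr is None:
            return 0.0
        chrom, ts, te = self.truth.sdr
        best = 0.0
        for r in self.regions:
            if r.chrom != chrom:
                continue
            inter = max(0, min(te, r.end) - max(ts, r.start))
            union = (te - ts) + (r.end - r.start) - inter
            if union > 0:
                best = max(best, inter / union)
        return best

    def autosomal_calls(self) -> List[CandidateRegion]:
        chrom = self.truth.sdr[0] if self.truth.sdr else None
        return [r for r in self.regions if r.chrom != chrom]


def _hashed_occurrences(rs: ReadSet, params: KmerParams) -> Tuple[np.ndarray, np.ndarray]:
    from ._kernels import HAVE_NUMBA, hashed_occurrences_numba

    if HAVE_NUMBA and rs.uniform_length and len(params.prefix) <= 2 and len(rs):
        return hashed_occurrences_numba(rs.matrix, params.k, params.prefix)
    windows, ridx = collect_kmer_occurrences(rs, params)
    return encode_kmers_int64(windows), ridx.astype(np.int64)


def _hashed_counts(h: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    if h.size == 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=np.int64)
    s = np.sort(h)
    new = np.empty(s.size, dtype=bool)
    new[0] = True
    new[1:] = s[1:] != s[:-1]
    starts = np.flatnonzero(new)
    return s[starts], np.diff(np.append(starts, s.size)).astype(np.int64)


def _classify_hashed(
    per_sample: Dict[str, Tuple[np.ndarray, np.ndarray]],
    sexes: Dict[str, str],
    params: KmerParams,
) -> Tuple[np.ndarray, np.ndarray]:
    """MSK/FSK hash sets from per-sample (unique hashes, counts)."""
    union = np.unique(np.concatenate([uh for uh, _ in per_sample.values()]))
    mat = np.zeros((union.size, len(per_sample)), dtype=np.int64)
    male = np.zeros(len(per_sample), dtype=bool)
    for j, (sid, (uh, c)) in enumerate(per_sample.items()):
        mat[np.searchsorted(union, uh), j] = c
        male[j] = sexes[sid] == "male"
    total = mat.sum(axis=1)
    valid = total > params.min_total_count
    zero_f = (mat[:, ~male] == 0).all(axis=1)
    zero_m = (mat[:, male] == 0).all(axis=1)
    if params.require_presence_all_focal:
        all_m = (mat[:, male] >= 1).all(axis=1)
        all_f = (mat[:, ~male] >= 1).all(axis=1)
    else:
        all_m = all_f = np.ones(mat.shape[0], dtype=bool)
    return union[valid & zero_f & all_m], union[valid & zero_m & all_f]


def _label_hashed(
    h: np.ndarray, ridx: np.ndarray, n_reads: int,
    msk_h: np.ndarray, fsk_h: np.ndarray, min_read_hits: int,
) -> Dict[str, np.ndarray]:
    def hits(catalog):
        out = np.zeros(n_reads, dtype=np.int64)
        if catalog.size and h.size:
            pos = np.searchsorted(catalog, h).clip(0, catalog.size - 1)
            np.add.at(out, ridx[catalog[pos] == h], 1)
        return out

    m_hits, f_hits = hits(msk_h), hits(fsk_h)
    t = min_read_hits
    male = (m_hits >= t) & (f_hits == 0)
    female = (f_hits >= t) & (m_hits == 0)
    ambiguous = (m_hits > 0) & (f_hits > 0)
    return {
        "male": np.flatnonzero(male),
        "female": np.flatnonzero(female),
        "ambiguous": np.flatnonzero(ambiguous),
        "unlabeled": np.flatnonzero(~(male | female | ambiguous)),
    }


def run_sdr_pipeline(
    genome_params: SimGenomeParams,
    read_params: ReadSimParams,
    kmer_params: Optional[KmerParams] = None,
    window: int = 100_000,
    z: float = 4.0,
    merge_gap: int = 2,
    min_windows: int = 2,
    max_mismatch: int = 2,
    engine: str = "hashed",
) -> SdrRunResult:
    """Simulate a sexed cohort and recover the SDR."""
    if kmer_params is None:
        kmer_params = KmerParams()
    genomes, truth = simulate_xy_genome(genome_params)
    read_sets = simulate_reads(genomes, read_params)
    sexes = {s: ("male" if s.startswith("M") else "female") for s in read_sets}

    male_assembly = genomes.male_assembly
    index = ReferenceIndex(male_assembly)
    chrom_lengths = genomes.chrom_lengths("male")

    label_sizes: Dict[str, Dict[str, int]] = {}
    male_placed: List = []
    female_placed: List = []

    if engine == "hashed":
        occ: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        counts: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for sid, rs in read_sets.items():
            h, ridx = _hashed_occurrences(rs, kmer_params)
            occ[sid] = (h, ridx)
            counts[sid] = _hashed_counts(h)
        msk_h, fsk_h = _classify_hashed(counts, sexes, kmer_params)
        n_msk, n_fsk = int(msk_h.size), int(fsk_h.size)
        for sid, rs in read_sets.items():
            h, ridx = occ.pop(sid)
            parts = _label_hashed(h, ridx, len(rs), msk_h, fsk_h, kmer_params.min_read_hits)
            label_sizes[sid] = {k: int(v.size) for k, v in parts.items()}
            male_placed.extend(place_reads(rs.subset(parts["male"]), index, max_mismatch=max_mismatch))
            female_placed.extend(place_reads(rs.subset(parts["female"]), index, max_mismatch=max_mismatch))
    elif engine == "exact":
        samples: List[SampleKmerCounts] = []
        for sid, rs in read_sets.items():
            windows, ridx = collect_kmer_occurrences(rs, kmer_params)
            kmers, cnt = _count_windows(windows, kmer_params.k)
            samples.append(SampleKmerCounts(sid, sexes[sid], kmers, cnt, k=kmer_params.k, prefix=kmer_params.prefix))
        sets = classify_sex_kmers(merge_samples(samples), kmer_params)
        n_msk, n_fsk = int(sets.msk.size), int(sets.fsk.size)
        for sid, rs in read_sets.items():
            labeled = label_reads(rs, sets, kmer_params)
            label_sizes[sid] = labeled.sizes()
            male_placed.extend(place_reads(labeled.partition("male"), index, max_mismatch=max_mismatch))
            female_placed.extend(place_reads(labeled.partition("female"), index, max_mismatch=max_mismatch))
    else:
        raise ValueError(f"unknown engine {engine!r}")

    male_track = window_depth(male_placed, chrom_lengths, window)
    female_track = window_depth(female_placed, chrom_lengths, window)
    regions = call_sdr(male_track, female_track, z=z, merge_gap=merge_gap, min_windows=min_windows)
    return SdrRunResult(
        truth=truth,
        regions=regions,
        n_msk=n_msk,
        n_fsk=n_fsk,
        label_sizes=label_sizes,
        male_track=male_track,
        female_track=female_track,
    )
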