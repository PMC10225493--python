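"""Prefix-subsampled k-mer cataloguing, sex-specific k-mer classification
and sex-specific read labeling.

K-mers are literal strings: no canonicalization before the prefix filter;
instead every read is scanned in both orientations (read and reverse
complement), which restores strand symmetry.  K-mers containing N are
dropped entirely.

Classification predicate (defaults k=40, prefix="AG", min_total_count=10):
a k-mer is male-specific iff its summed count over ALL samples is strictly
greater than min_total_count, its count is zero in every female sample,
and (by default) it is present in every male sample; female-specific is
symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._util import encode_kmers_int64, revcomp_bytes, window_view
from .readset import ReadSet, as_readset

_N = ord("N")


@dataclass
class KmerParams:
    k: int = 40
    prefix: str = "AG"
    min_total_count: int = 10  # validity rule is strict: total > min_total_count
    require_presence_all_focal: bool = True
    min_read_hits: int = 1

    def validate(self) -> None:
        if self.k <= len(self.prefix) or len(self.prefix) < 0:
            raise ValueError("need k > len(prefix) >= 0")
        if self.min_total_count < 0:
            raise ValueError("min_total_count must be >= 0")
        if self.min_read_hits < 1:
            raise ValueError("min_read_hits must be >= 1")


@dataclass
class SampleKmerCounts:
    sample_id: str
    sex: str  # "male" | "female"
    kmers: np.ndarray  # sorted S{k} array
    counts: np.ndarray  # int64, aligned with kmers
    k: int = 40
    prefix: str = "AG"

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")

    def to_dict(self) -> Dict[str, int]:
        return {km.decode(): int(c) for km, c in zip(self.kmers, self.counts)}

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.kmers.size

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tcount\n")
            for km, c in zip(self.kmers, self.counts):
                fh.write(f"{km.decode()}\t{int(c)}\n")

    @classmethod
    def from_tsv(cls, path, sample_id: str, sex: str) -> "SampleKmerCounts":
        kmers, counts = [], []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                km, c = line.split()
                kmers.append(km.encode())
                counts.append(int(c))
        k = len(kmers[0]) if kmers else 0
        arr = np.array(kmers, dtype=f"S{max(k,1)}")
        order = np.argsort(arr)
        return cls(sample_id, sex, arr[order], np.array(counts, dtype=np.int64)[order], k=k)


# ---------------------------------------------------------------- extraction


def _prefix_window_positions(mat: np.ndarray, k: int, prefix: bytes) -> Tuple[np.ndarray, np.ndarray]:
    """(row, col) of every k-window starting with ``prefix`` in a read matrix."""
    n, L = mat.shape
    if L < k:
        return np.array([], dtype=np.intp), np.array([], dtype=np.intp)
    limit = L - k + 1
    if prefix:
        mask = np.ones((n, limit), dtype=bool)
        for j, ch in enumerate(prefix):
            mask &= mat[:, j : j + limit] == ch
    else:
        mask = np.ones((n, limit), dtype=bool)
    return np.nonzero(mask)


def _gather_windows(mat: np.ndarray, rows: np.ndarray, cols: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Extract windows, dropping any containing N; returns (windows, kept_rows)."""
    if rows.size == 0:
        return np.zeros((0, k), dtype=np.uint8), rows
    flat = np.ascontiguousarray(mat).reshape(-1)
    win = window_view(flat, k)[rows * mat.shape[1] + cols]
    ok = ~(win == _N).any(axis=1)
    return win[ok], rows[ok]


def collect_kmer_occurrences(reads, params: KmerParams) -> Tuple[np.ndarray, np.ndarray]:
    """All prefix-matching k-mer occurrences over reads and their reverse
    complements: (windows uint8 (m, k), read_index (m,))."""
    params.validate()
    rs = as_readset(reads)
    prefix = params.prefix.encode()
    if len(rs) == 0:
        return np.zeros((0, params.k), dtype=np.uint8), np.array([], dtype=np.intp)
    if rs.uniform_length:
        mat = rs.matrix
        out_w, out_r = [], []
        for m in (mat, revcomp_bytes(mat)):
            rows, cols = _prefix_window_positions(m, params.k, prefix)
            win, rows = _gather_windows(m, rows, cols, params.k)
            out_w.append(win)
            out_r.append(rows)
        return np.concatenate(out_w), np.concatenate(out_r)
    # variable-length fallback
    windows: List[bytes] = []
    ridx: List[int] = []
    from ._util import revcomp

    p = params.prefix
    for i, seq in enumerate(rs):
        for s in (seq, revcomp(seq)):
            start = 0
            limit = len(s) - params.k
            while True:
                j = s.find(p, start) if p else start
                if j < 0 or j > limit:
                    break
                km = s[j : j + params.k]
                if "N" not in km:
                    windows.append(km.encode())
                    ridx.append(i)
                start = j + 1
                if not p and start > limit:
                    break
    if not windows:
        return np.zeros((0, params.k), dtype=np.uint8), np.array([], dtype=np.intp)
    arr = np.array(windows, dtype=f"S{params.k}").view(np.uint8).reshape(len(windows), params.k)
    return arr, np.array(ridx, dtype=np.intp)


def _count_windows(windows: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Exact multiset counts of the rows of a (m, k) uint8 matrix."""
    if windows.shape[0] == 0:
        return np.zeros(0, dtype=f"S{k}"), np.zeros(0, dtype=np.int64)
    as_s = np.ascontiguousarray(windows).view(f"S{k}").ravel()
    s = np.sort(as_s)
    sb = s.view(np.uint8).reshape(-1, k)
    new = np.empty(s.size, dtype=bool)
    new[0] = True
    new[1:] = (sb[1:] != sb[:-1]).any(axis=1)
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, s.size)).astype(np.int64)
    return s[starts], counts


def extract_prefix_kmers(reads, params: KmerParams, sample_id: str = "sample", sex: str = "male") -> SampleKmerCounts:
    """Count every k-length substring of each read and of its reverse
    complement that starts with the prefix and contains no N."""
    windows, _ = collect_kmer_occurrences(reads, params)
    kmers, counts = _count_windows(windows, params.k)
    return SampleKmerCounts(sample_id, sex, kmers, counts, k=params.k, prefix=params.prefix)


# ---------------------------------------------------------------- grouping


@dataclass
class GroupedCounts:
    kmers: np.ndarray  # sorted S{k}
    matrix: np.ndarray  # n_kmers x n_samples, int64
    sample_ids: List[str]
    sexes: List[str]
    k: int
    prefix: str

    @property
    def male_cols(self) -> np.ndarray:
        return np.array([s == "male" for s in self.sexes])

    def column_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def merge_samples(samples: Sequence[SampleKmerCounts]) -> GroupedCounts:
    if not samples:
        raise ValueError("no samples to merge")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    sexes = [s.sex for s in samples]
    if "male" not in sexes or "female" not in sexes:
        raise ValueError("need at least one sample per sex")
    ks = {s.k for s in samples}
    if len(ks) != 1:
        raise ValueError("samples counted with different k")
    k = ks.pop()
    union = np.unique(np.concatenate([s.kmers for s in samples]))
    mat = np.zeros((union.size, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        idx = np.searchsorted(union, s.kmers)
        mat[idx, j] = s.counts
    return GroupedCounts(union, mat, ids, sexes, k=k, prefix=samples[0].prefix)


# ---------------------------------------------------------------- classification


@dataclass
class SexKmerSets:
    msk: np.ndarray  # sorted S{k}
    fsk: np.ndarray
    msk_counts: np.ndarray  # retained count rows, n_msk x n_samples
    fsk_counts: np.ndarray
    sample_ids: List[str]
    sexes: List[str]
    k: int
    prefix: str

    def msk_set(self) -> set:
        return {x.decode() for x in self.msk}

    def fsk_set(self) -> set:
        return {x.decode() for x in self.fsk}

    def write_fasta(self, msk_path, fsk_path) -> None:
        from .io import write_fasta

        write_fasta(msk_path, ((f"MSK_{i}", km.decode()) for i, km in enumerate(self.msk)))
        write_fasta(fsk_path, ((f"FSK_{i}", km.decode()) for i, km in enumerate(self.fsk)))


def classify_sex_kmers(counts: GroupedCounts, params: KmerParams) -> SexKmerSets:
    """Apply the sex-specificity predicate to every k-mer of the grouped table."""
    params.validate()
    male = counts.male_cols
    if not male.any() or male.all():
        raise ValueError("need at least one sample of each sex")
    mat = counts.matrix
    if np.any(mat < 0):
        raise ValueError("negative k-mer counts")
    total = mat.sum(axis=1)
    valid = total > params.min_total_count
    zero_f = (mat[:, ~male] == 0).all(axis=1)
    zero_m = (mat[:, male] == 0).all(axis=1)
    if params.require_presence_all_focal:
        all_m = (mat[:, male] >= 1).all(axis=1)
        all_f = (mat[:, ~male] >= 1).all(axis=1)
    else:
        all_m = np.ones(mat.shape[0], dtype=bool)
        all_f = np.ones(mat.shape[0], dtype=bool)
    is_msk = valid & zero_f & all_m
    is_fsk = valid & zero_m & all_f
    return SexKmerSets(
        msk=counts.kmers[is_msk],
        fsk=counts.kmers[is_fsk],
        msk_counts=mat[is_msk],
        fsk_counts=mat[is_fsk],
        sample_ids=counts.sample_ids,
        sexes=counts.sexes,
        k=counts.k,
        prefix=counts.prefix,
    )


# ---------------------------------------------------------------- read labeling


@dataclass
class LabeledReads:
    reads: ReadSet
    male_idx: np.ndarray
    female_idx: np.ndarray
    ambiguous_idx: np.ndarray
    unlabeled_idx: np.ndarray

    def partition(self, which: str) -> ReadSet:
        return self.reads.subset(getattr(self, f"{which}_idx"))

    def sizes(self) -> Dict[str, int]:
        return {
            "male": self.male_idx.size,
            "female": self.female_idx.size,
            "ambiguous": self.ambiguous_idx.size,
            "unlabeled": self.unlabeled_idx.size,
        }


def _hit_counts(windows: np.ndarray, ridx: np.ndarray, n_reads: int, catalog: np.ndarray, k: int) -> np.ndarray:
    """Exact per-read hit counts of catalog k-mers (sorted S{k} array)."""
    hits = np.zeros(n_reads, dtype=np.int64)
    if catalog.size == 0 or windows.shape[0] == 0:
        return hits
    cat_hash = np.sort(encode_kmers_int64(catalog.view(np.uint8).reshape(-1, k)))
    win_hash = encode_kmers_int64(windows)
    pos = np.searchsorted(cat_hash, win_hash)
    pos = np.minimum(pos, cat_hash.size - 1)
    candidate = cat_hash[pos] == win_hash
    if k <= 32:
        # 2-bit packing is exact
        np.add.at(hits, ridx[candidate], 1)
        return hits
    # k > 32: hash may collide -> verify candidates by exact string compare
    cand_idx = np.flatnonzero(candidate)
    if cand_idx.size:
        cand_s = np.ascontiguousarray(windows[cand_idx]).view(f"S{k}").ravel()
        j = np.searchsorted(catalog, cand_s)
        j = np.minimum(j, catalog.size - 1)
        exact = catalog[j] == cand_s
        np.add.at(hits, ridx[cand_idx[exact]], 1)
    return hits


def label_reads(reads, sets: SexKmerSets, params: KmerParams, _occurrences=None) -> LabeledReads:
    """Partition reads by sex-specific k-mer content (both orientations).

    male-specific: >= min_read_hits MSK hits and zero FSK hits; female
    symmetric; hits in both catalogs -> ambiguous; neither -> unlabeled.
    ``_occurrences`` lets callers reuse a precomputed
    collect_kmer_occurrences result for the same reads/params.
    """
    params.validate()
    if sets.k != params.k or sets.prefix != params.prefix:
        raise ValueError("k/prefix mismatch between catalog and params")
    rs = as_readset(reads)
    windows, ridx = _occurrences if _occurrences is not None else collect_kmer_occurrences(rs, params)
    n = len(rs)
    m_hits = _hit_counts(windows, ridx, n, sets.msk, params.k)
    f_hits = _hit_counts(windows, ridx, n, sets.fsk, params.k)
    t = params.min_read_hits
    male = (m_hits >= t) & (f_hits == 0)
    female = (f_hits >= t) & (m_hits == 0)
    ambiguous = (m_hits > 0) & (f_hits > 0)
    unlabeled = ~(male | female | ambiguous)
    return LabeledReads(
        reads=rs,
        male_idx=np.flatnonzero(male),
        female_idx=np.flatnonzero(female),
        ambiguous_idx=np.flatnonzero(ambiguous),
        unlabeled_idx=np.flatnonzero(unlabeled),
    )
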