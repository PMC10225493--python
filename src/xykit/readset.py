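"""Read-set container shared by the simulator, k-mer and placement code.

Equal-length reads are held as a dense (n, L) uint8 matrix so downstream
k-mer extraction and placement can stay vectorized; variable-length sets
fall back to a list of strings.
"""

from __future__ import annotations

import gzip
from typing import Iterator, Sequence

import numpy as np

from ._util import array_to_seq


class ReadSet:
    """Ordered collection of named reads."""

    def __init__(self, ids, seqs):
        # ids: sequence of names, or a callable index -> name (lazy naming
        # for multi-million-read simulated sets)
        if callable(ids):
            self._ids = None
            self._id_maker = ids
        else:
            self._ids = list(ids)
            self._id_maker = None
        if isinstance(seqs, np.ndarray):
            if seqs.ndim != 2 or seqs.dtype != np.uint8:
                raise ValueError("matrix form must be a 2-D uint8 array")
            self._matrix = seqs
            self._seqs = None
        else:
            self._seqs = list(seqs)
            self._matrix = None
        if self._ids is not None and len(self._ids) != len(self):
            raise ValueError("ids and sequences differ in length")

    @property
    def ids(self):
        if self._ids is None:
            self._ids = [self._id_maker(i) for i in range(len(self))]
        return self._ids

    def read_id(self, i: int) -> str:
        if self._ids is not None:
            return self._ids[i]
        return self._id_maker(i)

    # -- construction -------------------------------------------------
    @classmethod
    def from_strings(cls, seqs: Sequence[str], ids: Sequence[str] | None = None) -> "ReadSet":
        seqs = list(seqs)
        if ids is None:
            ids = [f"read{i}" for i in range(len(seqs))]
        if seqs and len({len(s) for s in seqs}) == 1:
            mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
            return cls(ids, mat.reshape(len(seqs), -1).copy())
        return cls(ids, seqs)

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        opener = gzip.open if str(path).endswith(".gz") else open
        ids, seqs = [], []
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline()
                plus = fh.readline()
                qual = fh.readline()
                rec = len(ids)
                if not header.startswith("@") or not plus.startswith("+") or not qual.strip():
                    raise ValueError(f"malformed FASTQ record at index {rec} in {path}")
                ids.append(header[1:].split()[0])
                seqs.append(seq.strip().upper())
        return cls.from_strings(seqs, ids)

    # -- views ---------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            if not self._seqs:
                return np.zeros((0, 0), dtype=np.uint8)
            if len({len(s) for s in self._seqs}) != 1:
                raise ValueError("variable-length read set has no matrix form")
            self._matrix = np.frombuffer("".join(self._seqs).encode("ascii"), dtype=np.uint8).reshape(
                len(self._seqs), -1
            ).copy()
        return self._matrix

    @property
    def uniform_length(self) -> bool:
        if self._matrix is not None:
            return True
        return len({len(s) for s in self._seqs}) <= 1

    def sequence(self, i: int) -> str:
        if self._matrix is not None:
            return array_to_seq(self._matrix[i])
        return self._seqs[i]

    def __len__(self) -> int:
        return self._matrix.shape[0] if self._matrix is not None else len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        for i in range(len(self)):
            yield self.sequence(i)

    def subset(self, indices) -> "ReadSet":
        indices = np.asarray(indices, dtype=np.intp)
        ids = [self.read_id(int(i)) for i in indices]
        if self._matrix is not None:
            return ReadSet(ids, self._matrix[indices])
        return ReadSet(ids, [self._seqs[i] for i in indices])

    # -- I/O -----------------------------------------------------------
    def write_fastq(self, path, qual_char: str = "I") -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for name, seq in zip(self.ids, self):
                fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def as_readset(reads) -> ReadSet:
    """Accept a ReadSet, an iterable of sequence strings, or a FASTQ path."""
    if isinstance(reads, ReadSet):
        return reads
    if isinstance(reads, (str, bytes)) or hasattr(reads, "read"):
        raise TypeError("pass a ReadSet or an iterable of sequences; use ReadSet.from_fastq for files")
    return ReadSet.from_strings([str(s) for s in reads])
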