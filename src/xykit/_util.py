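"""Shared low-level helpers: RNG streams, byte-level sequence codecs, intervals."""

from __future__ import annotations

import numpy as np

BASES = b"ACGT"
_A, _C, _G, _T, _N = ord("A"), ord("C"), ord("G"), ord("T"), ord("N")

# byte -> complement byte, identity elsewhere (N stays N)
COMPLEMENT = np.arange(256, dtype=np.uint8)
for x, y in ((_A, _T), (_C, _G), (_G, _C), (_T, _A), (ord("a"), _T), (ord("c"), _G), (ord("g"), _C), (ord("t"), _A)):
    COMPLEMENT[x] = y

# byte -> 2-bit code; 255 marks non-ACGT
CODE4 = np.full(256, 255, dtype=np.uint8)
for i, x in enumerate((_A, _C, _G, _T)):
    CODE4[x] = i
    CODE4[ord(chr(x).lower())] = i

_COMPLEMENT_STR = bytes(COMPLEMENT).decode("latin-1")
_TRANS = str.maketrans("ACGTacgt", "TGCATGCA")


def rng_stream(seed: int, stream: str) -> np.random.Generator:
    """Independent generator per (seed, stream-name).

    Adding a new stream elsewhere never perturbs an existing one.
    """
    tag = int.from_bytes(stream.encode()[:8].ljust(8, b"\0"), "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,)))


def revcomp(seq: str) -> str:
    return seq.translate(_TRANS)[::-1]


def revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement each row of a (n, L) uint8 matrix."""
    return COMPLEMENT[arr[:, ::-1]]


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_sequence(rng: np.random.Generator, length: int, base_composition=(0.25, 0.25, 0.25, 0.25)) -> np.ndarray:
    p = np.asarray(base_composition, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("base_composition must be 4 non-negative frequencies summing to 1")
    base_arr = np.frombuffer(BASES, dtype=np.uint8)
    if np.allclose(p, 0.25):
        return base_arr[rng.integers(0, 4, size=length)]
    return base_arr[np.searchsorted(np.cumsum(p), rng.random(length), side="right").clip(0, 3)]


def mutate_sites(rng: np.random.Generator, arr: np.ndarray, idx: np.ndarray) -> None:
    """Substitute each position in ``idx`` with a uniformly chosen different base (in place)."""
    if idx.size == 0:
        return
    cur = CODE4[arr[idx]]
    shift = rng.integers(1, 4, size=idx.size)
    arr[idx] = np.frombuffer(BASES, dtype=np.uint8)[(cur + shift) % 4]


def bernoulli_positions(rng: np.random.Generator, size: int, rate: float, chunk: int = 8_000_000) -> np.ndarray:
    """Positions of Bernoulli(rate) hits over [0, size), drawn in chunks to
    bound transient memory."""
    if rate <= 0 or size == 0:
        return np.array([], dtype=np.int64)
    hits = []
    for lo in range(0, size, chunk):
        n = min(chunk, size - lo)
        hits.append(np.flatnonzero(rng.random(n) < rate) + lo)
    return np.concatenate(hits)


def window_view(flat: np.ndarray, k: int) -> np.ndarray:
    """Sliding k-window view over a 1-D uint8 array (no copy)."""
    return np.lib.stride_tricks.sliding_window_view(flat, k)


def encode_kmers_int64(windows: np.ndarray) -> np.ndarray:
    """64-bit polynomial fingerprint of each row of a (n, k) uint8 base matrix.

    Exact 2-bit packing when k <= 32; a rolling-multiplier hash otherwise
    (collisions possible, callers must verify exact matches).
    """
    k = windows.shape[1]
    h = np.zeros(windows.shape[0], dtype=np.uint64)
    mult = np.uint64(4) if k <= 32 else np.uint64(0x9E3779B97F4A7C15)
    for j in range(k):
        h *= mult
        h += CODE4[np.ascontiguousarray(windows[:, j])].astype(np.uint64)
    return h


def merge_intervals(intervals):
    """Merge overlapping/touching (start, end) half-open intervals; returns sorted list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def covered_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
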