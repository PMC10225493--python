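"""Numba kernels for the throughput-critical k-mer scanning paths.

These are drop-in accelerations of the numpy reference implementations in
``kmers``; tests assert agreement between the two routes.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_COMP = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP[x] = y


@njit(cache=True)
def _scan_occurrences(mat, comp, code, k, p0, p1, mult, out_hash, out_ridx):
    """Collect hashes of k-windows starting with the (<=2 byte) prefix over
    each row and its reverse complement.  Returns the number written."""
    n, L = mat.shape
    limit = L - k
    m = 0
    rc = np.empty(L, dtype=np.uint8)
    for i in range(n):
        for orient in range(2):
            if orient == 0:
                row = mat[i]
            else:
                for j in range(L):
                    rc[j] = comp[mat[i, L - 1 - j]]
                row = rc
            for s in range(limit + 1):
                if p0 >= 0 and row[s] != p0:
                    continue
                if p1 >= 0 and row[s + 1] != p1:
                    continue
                h = np.uint64(0)
                ok = True
                for j in range(k):
                    c = code[row[s + j]]
                    if c < 0:
                        ok = False
                        break
                    h = h * mult + np.uint64(c)
                if ok:
                    out_hash[m] = h
                    out_ridx[m] = i
                    m += 1
    return m


def hashed_occurrences_numba(mat: np.ndarray, k: int, prefix: str):
    """(hash uint64, read_index int64) of all prefix-matching k-mers over a
    uniform-length read matrix, both orientations, N-windows dropped."""
    if len(prefix) > 2:
        raise ValueError("numba scanner supports prefixes up to 2 bases")
    p = prefix.encode()
    p0 = p[0] if len(p) > 0 else -1
    p1 = p[1] if len(p) > 1 else -1
    mult = np.uint64(4) if k <= 32 else np.uint64(0x9E3779B97F4A7C15)
    n, L = mat.shape
    if L < k:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=np.int64)
    # chunk rows so the worst-case occurrence buffer stays modest
    chunk = max(1, 50_000)
    hashes, ridxs = [], []
    for lo in range(0, n, chunk):
        sub = mat[lo : lo + chunk]
        cap = 2 * sub.shape[0] * (L - k + 1)
        out_hash = np.empty(cap, dtype=np.uint64)
        out_ridx = np.empty(cap, dtype=np.int64)
        m = _scan_occurrences(sub, _COMP, _CODE, k, p0, p1, mult, out_hash, out_ridx)
        hashes.append(out_hash[:m].copy())
        ridxs.append(out_ridx[:m] + lo)
    return np.concatenate(hashes), np.concatenate(ridxs)


@njit(cache=True)
def _pack_ref(arr, code, k):
    """2-bit pack every k-window of a chromosome; -1 where non-ACGT."""
    m = arr.size - k + 1
    out = np.empty(m, dtype=np.int64)
    for s in range(m):
        h = np.int64(0)
        ok = True
        for j in range(k):
            c = code[arr[s + j]]
            if c < 0:
                ok = False
                break
            h = h * 4 + c
        out[s] = h if ok else -1
    return out


def pack_reference_windows(arr: np.ndarray, k: int) -> np.ndarray:
    return _pack_ref(arr, _CODE, k)
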