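"""LTR insertion dating: global pairwise alignment, Kimura two-parameter
distance (transitions P, transversions Q) and age T = K / (2r)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

DEFAULT_RATE = 1.8e-8  # substitutions per site per year

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class AgeParams:
    rate: float = DEFAULT_RATE

    def validate(self) -> None:
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")


@dataclass
class AlignedPair:
    seq5: str
    seq3: str
    n_ungapped: int
    score: Optional[int] = None

    def __post_init__(self):
        if len(self.seq5) != len(self.seq3):
            raise ValueError("aligned sequences must have equal length")
        if self.n_ungapped < 1:
            raise ValueError("alignment has no ungapped columns")


@dataclass
class K2PResult:
    p: float  # transition proportion
    q: float  # transversion proportion
    k: float  # substitutions per site
    n_sites: int  # comparable (ungapped, N-free) columns


class SaturationError(ValueError):
    """K2P log arguments non-positive: divergence beyond the estimable range."""


def align_ltrs(seq5: str, seq3: str, prealigned: bool = False) -> AlignedPair:
    """Global alignment with match +1, mismatch -1, gap -2.

    Traceback tie-breaking is deterministic: diagonal preferred, then up
    (gap in the second sequence), then left.  Inputs already containing
    '-' (or flagged prealigned) are accepted verbatim.
    """
    seq5, seq3 = seq5.upper(), seq3.upper()
    if not seq5 or not seq3:
        raise ValueError("empty sequence")
    if prealigned or "-" in seq5 or "-" in seq3:
        if len(seq5) != len(seq3):
            raise ValueError("prealigned sequences must have equal length")
        n_ungapped = sum(1 for a, b in zip(seq5, seq3) if a != "-" and b != "-")
        pair = AlignedPair(seq5, seq3, max(n_ungapped, 1))
        pair.n_ungapped = n_ungapped
        _require_informative(pair)
        return pair
    a5, a3, score = _needleman_wunsch(seq5, seq3)
    n_ungapped = sum(1 for a, b in zip(a5, a3) if a != "-" and b != "-")
    pair = AlignedPair(a5, a3, n_ungapped, score=score)
    _require_informative(pair)
    return pair


def _require_informative(pair: AlignedPair) -> None:
    informative = sum(
        1
        for a, b in zip(pair.seq5, pair.seq3)
        if a != "-" and b != "-" and a != "N" and b != "N"
    )
    if informative < 1:
        raise ValueError("no informative (ungapped, non-N) columns in alignment")


MATCH, MISMATCH, GAP = 1, -1, -2


def _needleman_wunsch(a: str, b: str) -> Tuple[str, str, int]:
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = GAP * np.arange(m + 1)
    H[:, 0] = GAP * np.arange(n + 1)
    j_idx = np.arange(m)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], MATCH, MISMATCH)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP)
        # left-gap closure: H[i, j] = max_k<=j (cand[k] - 2*(j-k)); prefix max trick
        run = np.maximum.accumulate(cand - GAP * j_idx)
        H[i, 1:] = run + GAP * j_idx
    # traceback with fixed preference: diagonal, then up, then left
    i, j = n, m
    out_a: List[str] = []
    out_b: List[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + GAP:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(H[n, m])


def k2p_distance(pair: AlignedPair) -> K2PResult:
    """K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) over comparable columns.

    Columns containing a gap or an N are excluded pairwise.
    """
    ts = tv = total = 0
    for x, y in zip(pair.seq5, pair.seq3):
        if x in "-N" or y in "-N":
            continue
        total += 1
        if x == y:
            continue
        if (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if total == 0:
        raise ValueError("no comparable columns")
    p, q = ts / total, tv / total
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P saturated: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}")
    k = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(p=p, q=q, k=k, n_sites=total)


def insertion_age(k2p: K2PResult, params: AgeParams = AgeParams()) -> float:
    """T = K / (2r), in years."""
    params.validate()
    if not math.isfinite(k2p.k):
        raise ValueError("non-finite K2P distance")
    return k2p.k / (2.0 * params.rate)


# ---------------------------------------------------------------- batch mode


def pair_records(fasta_records: Dict[str, str]) -> Dict[str, Tuple[str, str]]:
    """Group '<element>_5p' / '<element>_3p' FASTA records into pairs."""
    pairs: Dict[str, Dict[str, str]] = {}
    for name, seq in fasta_records.items():
        if name.endswith("_5p"):
            pairs.setdefault(name[:-3], {})["5"] = seq
        elif name.endswith("_3p"):
            pairs.setdefault(name[:-3], {})["3"] = seq
        else:
            raise ValueError(f"record {name!r} lacks _5p/_3p suffix")
    out = {}
    for element, d in sorted(pairs.items()):
        if set(d) != {"5", "3"}:
            raise ValueError(f"element {element!r} is missing one LTR")
        out[element] = (d["5"], d["3"])
    return out


def date_pairs(
    pairs: Dict[str, Tuple[str, str]],
    params: AgeParams = AgeParams(),
    prealigned: bool = False,
) -> pd.DataFrame:
    rows = []
    for element, (s5, s3) in pairs.items():
        aln = align_ltrs(s5, s3, prealigned=prealigned)
        try:
            res = k2p_distance(aln)
            rows.append((element, res.p, res.q, res.k, insertion_age(res, params)))
        except SaturationError:
            rows.append((element, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["element", "P", "Q", "K", "T_years"])


def age_histogram(ages_years: Iterable[float], bin_mya: float = 0.1) -> pd.DataFrame:
    ages = np.asarray([a for a in ages_years if np.isfinite(a)]) / 1e6
    if ages.size == 0:
        return pd.DataFrame(columns=["bin_start_mya", "bin_end_mya", "count"])
    n_bins = int(np.ceil(ages.max() / bin_mya)) or 1
    edges = np.arange(n_bins + 1) * bin_mya
    counts, _ = np.histogram(ages, bins=edges)
    return pd.DataFrame(
        {"bin_start_mya": edges[:-1], "bin_end_mya": edges[1:], "count": counts}
    )
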