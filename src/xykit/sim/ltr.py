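"""Simulate 5'/3' LTR pairs diverged for a known time under a two-parameter model.

Each copy accumulates Poisson(r*T) substitution events per site; each event
is a transition with probability kappa/(kappa+2), otherwise one of the two
transversions.  Expected pairwise divergence (before multiple-hit
correction) is therefore ~ 2*r*T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .._util import BASES, CODE4, array_to_seq, random_sequence, rng_stream

# 2-bit codes: A=0 C=1 G=2 T=3; transition partner swaps A<->G, C<->T
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion targets per base
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


@dataclass
class LtrSimParams:
    age_years: float = 1_000_000.0
    rate: float = 1.8e-8  # substitutions per site per year
    length: int = 5_000
    kappa: float = 2.0  # transition:transversion rate ratio
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def validate(self) -> None:
        if self.age_years < 0 or self.rate < 0 or self.length <= 0:
            raise ValueError("age_years, rate must be >= 0 and length positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def _evolve(rng: np.random.Generator, codes: np.ndarray, mean_subs: float, kappa: float) -> np.ndarray:
    out = codes.copy()
    n_events = rng.poisson(mean_subs, size=codes.size)
    remaining = n_events.copy()
    while remaining.max(initial=0) > 0:
        live = np.flatnonzero(remaining > 0)
        is_ts = rng.random(live.size) < kappa / (kappa + 2.0)
        cur = out[live]
        nxt = np.where(
            is_ts,
            _TRANSITION[cur],
            _TRANSVERSIONS[cur, rng.integers(0, 2, size=live.size)],
        )
        out[live] = nxt
        remaining[live] -= 1
    return out


def simulate_ltr_pair(params: LtrSimParams) -> Tuple[str, str]:
    """Return (ltr5, ltr3): two descendants of one ancestral LTR sequence."""
    params.validate()
    rng = rng_stream(params.seed, "ltr-pair")
    ancestral = random_sequence(rng, params.length, params.base_composition)
    codes = CODE4[ancestral]
    mean_subs = params.rate * params.age_years
    base_arr = np.frombuffer(BASES, dtype=np.uint8)
    five = array_to_seq(base_arr[_evolve(rng, codes, mean_subs, params.kappa)])
    three = array_to_seq(base_arr[_evolve(rng, codes, mean_subs, params.kappa)])
    return five, three
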