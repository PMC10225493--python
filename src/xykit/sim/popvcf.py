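"""Simulate wild/domestic diploid genotype matrices with planted sweep windows.

Neutral sites: ancestral frequency p ~ Beta(a, b); the wild population keeps
p, the domestic population gets p plus truncated-normal drift.  Sweep
windows push domestic frequencies to near-fixation (below EPSILON or above
1 - EPSILON) with probability ``sweep_prob`` per site, and thin site density
by ``site_thinning``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np

from .._util import rng_stream
from ..io import write_vcf
from ..popgen import GenotypeMatrix
from .truth import TruthSet

EPSILON = 0.01  # near-fixation margin for swept sites


@dataclass
class SimPopParams:
    genome_length: int = 100_000_000
    window: int = 50_000
    n_wild: int = 12
    n_dom: int = 40
    beta_a: float = 0.8
    beta_b: float = 0.8
    drift_sd: float = 0.05
    sweep_windows: Union[int, Sequence[int]] = 20  # count, or explicit window indices
    sweep_prob: float = 0.9
    site_thinning: float = 0.1
    sites_per_window: int = 40
    chrom: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0 or self.window <= 0:
            raise ValueError("genome_length and window must be positive")
        if self.n_wild <= 0 or self.n_dom <= 0:
            raise ValueError("need at least one diploid per population")
        if not 0 < self.site_thinning <= 1:
            raise ValueError("site_thinning must lie in (0, 1]")
        if not 0 <= self.sweep_prob <= 1:
            raise ValueError("sweep_prob must lie in [0, 1]")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")

    @property
    def n_windows(self) -> int:
        return (self.genome_length + self.window - 1) // self.window


def _truncated_normal(rng: np.random.Generator, sd: float, size: int, lo: float, hi: float) -> np.ndarray:
    """Rejection-sampled N(0, sd) increments; per-site bounds applied by caller clipping."""
    if sd == 0:
        return np.zeros(size)
    return rng.normal(0.0, sd, size=size)


def simulate_population_vcf(
    params: SimPopParams,
    vcf_path=None,
    truth_bed_path=None,
) -> Tuple[GenotypeMatrix, TruthSet]:
    params.validate()
    rng = rng_stream(params.seed, "pop-vcf")
    n_win = params.n_windows

    if isinstance(params.sweep_windows, (int, np.integer)):
        k = int(params.sweep_windows)
        if k > n_win:
            raise ValueError("more sweep windows requested than windows available")
        sweep_idx = np.sort(rng.choice(n_win, size=k, replace=False))
    else:
        sweep_idx = np.array(sorted(int(i) for i in params.sweep_windows), dtype=int)
        if sweep_idx.size and (sweep_idx[0] < 0 or sweep_idx[-1] >= n_win):
            raise ValueError("sweep window index out of range")
    sweep_mask_win = np.zeros(n_win, dtype=bool)
    sweep_mask_win[sweep_idx] = True

    # site positions: uniform draws per window, thinned inside sweep windows
    pos_blocks: List[np.ndarray] = []
    win_of_site: List[np.ndarray] = []
    for w in range(n_win):
        lo = w * params.window
        hi = min(lo + params.window, params.genome_length)
        n_sites = params.sites_per_window
        if sweep_mask_win[w]:
            n_sites = int(rng.binomial(n_sites, params.site_thinning))
        if n_sites == 0:
            continue
        p = np.sort(rng.choice(hi - lo, size=min(n_sites, hi - lo), replace=False)) + lo
        pos_blocks.append(p)
        win_of_site.append(np.full(p.size, w))
    pos0 = np.concatenate(pos_blocks) if pos_blocks else np.array([], dtype=int)
    site_win = np.concatenate(win_of_site) if win_of_site else np.array([], dtype=int)
    m = pos0.size

    n_wild_alleles = 2 * params.n_wild
    p_anc = rng.beta(params.beta_a, params.beta_b, size=m)
    lo_f, hi_f = 1.0 / n_wild_alleles, 1.0 - 1.0 / n_wild_alleles
    p_wild = np.clip(p_anc, lo_f, hi_f)
    drift = _truncated_normal(rng, params.drift_sd, m, lo_f, hi_f)
    p_dom = np.clip(p_wild + drift, lo_f, hi_f)

    swept_site = sweep_mask_win[site_win] & (rng.random(m) < params.sweep_prob)
    p_dom = np.where(swept_site, np.where(p_wild >= 0.5, 1.0 - EPSILON, EPSILON), p_dom)

    g_wild = rng.binomial(2, p_wild[:, None], size=(m, params.n_wild))
    g_dom = rng.binomial(2, p_dom[:, None], size=(m, params.n_dom))
    dosages = np.concatenate([g_wild, g_dom], axis=1).astype(np.int8)

    samples = [f"W{i+1}" for i in range(params.n_wild)] + [f"D{i+1}" for i in range(params.n_dom)]
    pops = ["wild"] * params.n_wild + ["dom"] * params.n_dom
    gm = GenotypeMatrix(
        chrom=params.chrom,
        pos=pos0 + 1,  # 1-based, VCF convention
        dosages=dosages,
        samples=samples,
        pops=np.array(pops),
        ref_len=np.ones(m, dtype=int),
        alt_len=np.ones(m, dtype=int),
        n_alt=np.ones(m, dtype=int),
    )

    truth = TruthSet(
        sweep_windows=[
            (params.chrom, int(w) * params.window, min((int(w) + 1) * params.window, params.genome_length))
            for w in sweep_idx
        ]
    )

    if vcf_path is not None:
        _REF = np.array(["A"] * m)
        _ALT = np.array(["G"] * m)
        write_vcf(
            vcf_path, params.chrom, gm.pos, _REF, _ALT, dosages, samples,
            chrom_lengths={params.chrom: params.genome_length},
        )
    if truth_bed_path is not None:
        truth.write_sweep_bed(truth_bed_path)
    return gm, truth
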