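"""Windowed population-genetic statistics and dual-outlier sweep selection.

FST follows Weir & Cockerham (1984) variance components a (among
populations), b (among individuals within populations) and c (within
individuals); pi uses the unbiased per-site estimator 2j(n-j)/(n(n-1))
divided by full window length; Tajima's D uses the standard constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import read_gff3_genes


@dataclass
class SweepParams:
    window: int = 50_000
    step: int = 50_000
    quantile: float = 0.99
    min_sites: int = 1
    maf_floor: float = 0.05
    max_missing: float = 0.1
    min_segregating: int = 3  # Tajima's D minimum S per window

    def validate(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if self.step > self.window or self.step <= 0:
            raise ValueError("0 < step <= window required")


@dataclass
class GenotypeMatrix:
    """Biallelic-dosage view of one chromosome of a multi-sample VCF."""

    chrom: str
    pos: np.ndarray  # 1-based positions, strictly increasing
    dosages: np.ndarray  # sites x samples, int8, {0,1,2}, -1 missing
    samples: List[str]
    pops: np.ndarray  # population label per sample
    ref_len: np.ndarray
    alt_len: np.ndarray
    n_alt: np.ndarray  # ALT allele count per site (1 = biallelic)

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.pos.size and np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.dosages.shape != (self.pos.size, len(self.samples)):
            raise ValueError("dosage matrix shape mismatch")

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(self.pops == pop)
        if idx.size == 0:
            raise ValueError(f"no samples in population {pop!r}")
        return idx

    def take_sites(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom,
            pos=self.pos[mask],
            dosages=self.dosages[mask],
            samples=self.samples,
            pops=self.pops,
            ref_len=np.asarray(self.ref_len)[mask],
            alt_len=np.asarray(self.alt_len)[mask],
            n_alt=np.asarray(self.n_alt)[mask],
        )

    @classmethod
    def from_vcf(cls, path, pop_labels: Dict[str, str], chrom: Optional[str] = None) -> "GenotypeMatrix":
        """Read a (possibly multi-allelic) VCF with pysam; keeps all sites,
        recording ALT count so site_filter can enforce biallelism."""
        import pysam

        vf = pysam.VariantFile(str(path))
        samples = list(vf.header.samples)
        missing = set(pop_labels) - set(samples)
        if missing:
            raise ValueError(f"samples in labels missing from VCF: {sorted(missing)}")
        pos, dos, rl, al, na = [], [], [], [], []
        the_chrom = chrom
        for rec in vf:
            if the_chrom is None:
                the_chrom = rec.chrom
            if rec.chrom != the_chrom:
                raise ValueError("GenotypeMatrix holds one chromosome; filter the VCF or pass chrom=")
            row = np.full(len(samples), -1, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                row[i] = sum(1 for a in gt if a != 0)
            pos.append(rec.pos)
            dos.append(row)
            alts = rec.alts or ()
            rl.append(len(rec.ref))
            al.append(len(alts[0]) if alts else 0)
            na.append(len(alts))
        pops = np.array([pop_labels.get(s, "") for s in samples])
        m = len(pos)
        return cls(
            chrom=the_chrom or (chrom or ""),
            pos=np.array(pos, dtype=np.int64),
            dosages=np.array(dos, dtype=np.int8).reshape(m, len(samples)),
            samples=samples,
            pops=pops,
            ref_len=np.array(rl, dtype=int),
            alt_len=np.array(al, dtype=int),
            n_alt=np.array(na, dtype=int),
        )


# ---------------------------------------------------------------- filters


def site_filter(g: GenotypeMatrix, params: SweepParams) -> GenotypeMatrix:
    """Keep biallelic sites with MAF >= maf_floor and missing fraction < max_missing."""
    called = g.dosages >= 0
    n_called = called.sum(axis=1)
    alt = np.where(called, g.dosages, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    n_samples = g.dosages.shape[1]
    miss_frac = (n_samples - n_called) / n_samples  # exact at the boundary
    keep = (np.asarray(g.n_alt) == 1) & (maf >= params.maf_floor) & (miss_frac < params.max_missing)
    return g.take_sites(keep)


# ---------------------------------------------------------------- windows


def window_grid(chrom_length: int, window: int, step: Optional[int] = None) -> np.ndarray:
    """(n, 2) array of 0-based half-open window bounds tiling [0, chrom_length)."""
    if window <= 0:
        raise ValueError("window length must be positive")
    step = step or window
    starts = np.arange(0, chrom_length, step)
    ends = np.minimum(starts + window, chrom_length)
    keep = ends > starts
    return np.stack([starts[keep], ends[keep]], axis=1)


def _assign_windows(pos: np.ndarray, grid: np.ndarray) -> List[np.ndarray]:
    """Site indices per window (pos is 1-based; grid 0-based half-open)."""
    p0 = pos - 1
    return [np.flatnonzero((p0 >= s) & (p0 < e)) for s, e in grid]


def _site_pi(dos: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site pi (allele-pair form) and called-allele counts from a dosage block."""
    called = dos >= 0
    n = 2 * called.sum(axis=1)
    j = np.where(called, dos, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * j * (n - j) / (n * (n - 1.0)), 0.0)
    return pi, n


def window_pi(
    g: GenotypeMatrix, pop: str, params: SweepParams, chrom_length: int
) -> pd.DataFrame:
    """Per-window nucleotide diversity: sum of site pi / window length (bp)."""
    grid = window_grid(chrom_length, params.window, params.step)
    idx = g.pop_indices(pop)
    pi_site, _ = _site_pi(g.dosages[:, idx])
    rows = []
    for (s, e), sites in zip(grid, _assign_windows(g.pos, grid)):
        length = e - s
        rows.append((g.chrom, s, e, sites.size, float(pi_site[sites].sum()) / length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"])


# ---------------------------------------------------------------- FST


def wc_fst_components(g: GenotypeMatrix, pops: Sequence[str]) -> pd.DataFrame:
    """Per-site Weir-Cockerham (1984) a, b, c for two (or more) populations.

    Sites where every population is monomorphic for the same allele get
    a = b = c = 0 and are flagged ``zero_denominator``.
    """
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    r = len(pops)
    m = g.n_sites
    n_i = np.zeros((m, r))
    p_i = np.zeros((m, r))
    h_i = np.zeros((m, r))
    for k, pop in enumerate(pops):
        idx = g.pop_indices(pop)
        dos = g.dosages[:, idx]
        called = dos >= 0
        n = called.sum(axis=1).astype(float)
        if np.any(n < 2):
            # W&C needs >= 2 individuals per population at a site; flag later
            pass
        alt = np.where(called, dos, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * n), 0.0)
            h = np.where(n > 0, (dos == 1).sum(axis=1) / n, 0.0)
        n_i[:, k] = n
        p_i[:, k] = p
        h_i[:, k] = h

    nbar = n_i.mean(axis=1)
    valid = (n_i >= 1).all(axis=1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=1) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=1) / (r * nbar)
        s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=1) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    denom = a + b + c
    return pd.DataFrame(
        {
            "pos": g.pos,
            "a": a,
            "b": b,
            "c": c,
            "zero_denominator": denom == 0.0,
        }
    )


def window_fst_wc(
    g: GenotypeMatrix,
    pops: Sequence[str],
    params: SweepParams,
    chrom_length: int,
    site_components: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-window weighted (ratio-of-sums) and mean (of ratios) W&C FST.

    Negative estimates are reported as computed; windows with no usable
    sites get NaN.
    """
    comps = site_components if site_components is not None else wc_fst_components(g, pops)
    grid = window_grid(chrom_length, params.window, params.step)
    a = comps["a"].to_numpy()
    abc = a + comps["b"].to_numpy() + comps["c"].to_numpy()
    usable = ~comps["zero_denominator"].to_numpy()
    rows = []
    for (s, e), sites in zip(grid, _assign_windows(g.pos, grid)):
        use = sites[usable[sites]]
        if use.size == 0:
            rows.append((g.chrom, s, e, 0, np.nan, np.nan))
            continue
        fw = a[use].sum() / abc[use].sum()
        fm = float(np.mean(a[use] / abc[use]))
        rows.append((g.chrom, s, e, use.size, fw, fm))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "fst_weighted", "fst_mean"])


# ---------------------------------------------------------------- Tajima's D


@dataclass
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ValueError("Tajima constants need n >= 2 alleles")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def window_tajima_d(
    g: GenotypeMatrix, pop: str, params: SweepParams, chrom_length: int
) -> pd.DataFrame:
    """Per-window Tajima's D; NaN where S < min_segregating.

    Sample size for the constants is the median called-allele count over the
    window's segregating sites (with complete data this is simply 2 x the
    number of individuals).
    """
    grid = window_grid(chrom_length, params.window, params.step)
    idx = g.pop_indices(pop)
    if 2 * idx.size < 2:
        raise ValueError("Tajima's D needs >= 2 alleles")
    dos = g.dosages[:, idx]
    pi_site, n_alleles = _site_pi(dos)
    called = dos >= 0
    j = np.where(called, dos, 0).sum(axis=1)
    seg = (j > 0) & (j < n_alleles) & (n_alleles >= 2)
    rows = []
    for (s, e), sites in zip(grid, _assign_windows(g.pos, grid)):
        seg_sites = sites[seg[sites]]
        S = seg_sites.size
        if S < params.min_segregating:
            rows.append((g.chrom, s, e, S, np.nan))
            continue
        n = int(np.median(n_alleles[seg_sites]))
        k = tajima_constants(n)
        theta_pi = float(pi_site[seg_sites].sum())
        theta_w = S / k.a1
        var = k.e1 * S + k.e2 * S * (S - 1)
        num = theta_pi - theta_w
        # n=2 alleles: variance constants vanish and the numerator is
        # identically 0, so D is 0 by continuity
        d = num / math.sqrt(var) if var > 0 else (0.0 if num == 0 else np.nan)
        rows.append((g.chrom, s, e, S, d))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_segregating", "tajima_d"])


# ---------------------------------------------------------------- ln-ratio & sweeps


def pi_ln_ratio(pi_wild: pd.DataFrame, pi_dom: pd.DataFrame, min_sites: int = 1) -> pd.DataFrame:
    """Elementwise ln(pi_wild / pi_dom); NaN where either window has too few
    sites or pi_dom is 0."""
    if not (
        len(pi_wild) == len(pi_dom)
        and (pi_wild["start"].to_numpy() == pi_dom["start"].to_numpy()).all()
        and (pi_wild["end"].to_numpy() == pi_dom["end"].to_numpy()).all()
    ):
        raise ValueError("window grids differ between the two pi tracks")
    pw = pi_wild["pi"].to_numpy()
    pd_ = pi_dom["pi"].to_numpy()
    ok = (
        (pi_wild["n_sites"].to_numpy() >= min_sites)
        & (pi_dom["n_sites"].to_numpy() >= min_sites)
        & (pd_ > 0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(ok, np.log(np.where(pw > 0, pw, np.nan) / np.where(ok, pd_, 1.0)), np.nan)
    out = pi_wild[["chrom", "start", "end"]].copy()
    out["pi_ln_ratio"] = val
    return out


def nearest_rank_above_threshold(values: np.ndarray, q: float) -> float:
    """Conservative empirical q-quantile: the value at rank ceil(q*m) (0-based)
    of the sorted non-NaN values, so at most floor((1-q)*m) values lie at or
    above the threshold-exceeding rank."""
    vals = np.sort(values[~np.isnan(values)])
    m = vals.size
    if m == 0:
        raise ValueError("all windows are NaN")
    idx = min(int(math.ceil(q * m)), m - 1)
    return float(vals[idx])


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    window_indices: List[int]
    mean_fst: float
    mean_ln_ratio: float
    genes: List[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.window_indices)


def select_sweeps(fst: pd.DataFrame, lnratio: pd.DataFrame, params: SweepParams) -> List[SweepRegion]:
    """Dual top-quantile outlier windows, merged when overlapping or adjacent."""
    if not (
        len(fst) == len(lnratio)
        and (fst["start"].to_numpy() == lnratio["start"].to_numpy()).all()
    ):
        raise ValueError("FST and ln-ratio tracks are on different grids")
    f = fst["fst_weighted"].to_numpy(dtype=float)
    l = lnratio["pi_ln_ratio"].to_numpy(dtype=float)
    t_f = nearest_rank_above_threshold(f, params.quantile)
    t_l = nearest_rank_above_threshold(l, params.quantile)
    outlier = np.zeros(len(fst), dtype=bool)
    with np.errstate(invalid="ignore"):
        outlier = (~np.isnan(f)) & (~np.isnan(l)) & (f >= t_f) & (l >= t_l)
    regions: List[SweepRegion] = []
    chroms = fst["chrom"].to_numpy()
    starts = fst["start"].to_numpy()
    ends = fst["end"].to_numpy()
    cur: Optional[SweepRegion] = None
    for i in np.flatnonzero(outlier):
        if cur is not None and chroms[i] == cur.chrom and starts[i] <= cur.end:
            cur.end = int(ends[i])
            cur.window_indices.append(int(i))
        else:
            if cur is not None:
                regions.append(cur)
            cur = SweepRegion(str(chroms[i]), int(starts[i]), int(ends[i]), [int(i)], 0.0, 0.0)
    if cur is not None:
        regions.append(cur)
    for reg in regions:
        wi = reg.window_indices
        reg.mean_fst = float(np.mean(f[wi]))
        reg.mean_ln_ratio = float(np.mean(l[wi]))
    return regions


def overlap_genes(regions: List[SweepRegion], gff3_path) -> List[SweepRegion]:
    """Attach gene ids with >= 1 bp overlap (GFF3 1-based inclusive converted
    to 0-based half-open on ingestion)."""
    genes = read_gff3_genes(gff3_path)
    for reg in regions:
        reg.genes = [
            gid
            for gid, chrom, s, e in genes
            if chrom == reg.chrom and min(e, reg.end) > max(s, reg.start)
        ]
    return regions


def allele_pattern_matrix(g: GenotypeMatrix, ref_pop: str, maf_floor: float = 0.05) -> pd.DataFrame:
    """Major/minor allele coding relative to the reference population, for
    haplotype-pattern style exports (no phasing)."""
    idx = g.pop_indices(ref_pop)
    pi_site, n = _site_pi(g.dosages[:, idx])
    called = g.dosages[:, idx] >= 0
    j = np.where(called, g.dosages[:, idx], 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, j / n, 0.0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf > maf_floor
    major_is_alt = freq[keep] > 0.5
    dos = g.dosages[keep]
    coded = np.where(dos < 0, -1, np.where(major_is_alt[:, None], 2 - dos, dos))
    df = pd.DataFrame(coded, columns=g.samples)
    df.insert(0, "pos", g.pos[keep])
    df.insert(0, "chrom", g.chrom)
    return df
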