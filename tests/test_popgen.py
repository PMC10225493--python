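import math

import numpy as np
import pandas as pd
import pytest

from xykit.popgen import (
    GenotypeMatrix,
    SweepParams,
    allele_pattern_matrix,
    nearest_rank_above_threshold,
    overlap_genes,
    pi_ln_ratio,
    select_sweeps,
    site_filter,
    tajima_constants,
    wc_fst_components,
    window_fst_wc,
    window_grid,
    window_pi,
    window_tajima_d,
)

# ---------------------------------------------------------------- oracles


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Independent two-population Weir & Cockerham (1984) a, b, c from
    sample sizes, allele frequencies and heterozygote frequencies."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def pairwise_pi_oracle(dosages):
    """Mean pairwise allele differences per site, brute force over all allele
    pairs reconstructed from dosages (order within a het is irrelevant)."""
    total = 0.0
    for row in dosages:
        alleles = []
        for d in row:
            if d >= 0:
                alleles.extend([1] * d + [0] * (2 - d))
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(
            1 for i in range(n) for j in range(i + 1, n) if alleles[i] != alleles[j]
        )
        total += diffs / (n * (n - 1) / 2)
    return total


def tajima_oracle(dosages, min_S=3):
    """Independent Tajima's D from a complete-data dosage block."""
    dosages = np.asarray(dosages)
    n = 2 * dosages.shape[1]
    j = dosages.sum(axis=1)
    seg = (j > 0) & (j < n)
    S = int(seg.sum())
    if S < min_S:
        return math.nan
    theta_pi = sum(2 * jj * (n - jj) / (n * (n - 1)) for jj in j[seg])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (theta_pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def make_matrix(dosages, pops, positions=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[0]
    pos = np.asarray(positions) if positions is not None else np.arange(1, m + 1) * 10
    return GenotypeMatrix(
        chrom=chrom,
        pos=pos,
        dosages=dosages,
        samples=[f"s{i}" for i in range(dosages.shape[1])],
        pops=np.asarray(pops),
        ref_len=np.ones(m, dtype=int),
        alt_len=np.ones(m, dtype=int),
        n_alt=np.ones(m, dtype=int),
    )


# ---------------------------------------------------------------- site filter


def test_site_filter_hand_matrix():
    pops = ["a"] * 5 + ["b"] * 5
    dosages = [
        [0] * 10,                      # monomorphic -> MAF 0, removed
        [2] * 10,                      # monomorphic ALT, removed
        [1] + [0] * 9,                 # MAF 0.05, kept (>=)
        [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],  # MAF 0.2, kept
        [0, 0, 0, 0, 0, 0, 0, 0, 0, -1],  # missing 0.1, not < 0.1 -> removed anyway MAF 0
        [1, 1, 0, 0, 0, 0, 0, 0, 0, -1],  # missing 0.1 -> removed (rate not < 0.1)
        [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],   # kept
    ]
    g = make_matrix(dosages, pops)
    out = site_filter(g, SweepParams())
    assert out.pos.tolist() == [30, 40, 70]


def test_site_filter_biallelic_only():
    g = make_matrix([[1, 1, 0, 0]], ["a", "a", "b", "b"])
    g.n_alt = np.array([2])  # multi-allelic
    assert site_filter(g, SweepParams()).n_sites == 0


def test_site_filter_empty():
    g = make_matrix(np.zeros((0, 4), dtype=np.int8), ["a", "a", "b", "b"])
    assert site_filter(g, SweepParams()).n_sites == 0


# ---------------------------------------------------------------- pi


def test_window_pi_single_site_example():
    # n=4 alleles, j=2 in a 100-bp window: site pi = 2*2*2/(4*3) = 0.6667
    g = make_matrix([[1, 1]], ["a", "a"], positions=[5])
    out = window_pi(g, "a", SweepParams(window=100, step=100), chrom_length=100)
    assert out["pi"][0] == pytest.approx(2 * 2 * 2 / (4 * 3) / 100, abs=1e-15)


def test_window_pi_no_variants_zero():
    g = make_matrix(np.zeros((0, 4), dtype=np.int8), ["a"] * 4)
    out = window_pi(g, "a", SweepParams(window=50, step=50), chrom_length=200)
    assert (out["pi"] == 0).all() and len(out) == 4


def test_window_pi_matches_pairwise_oracle(rng):
    pops = ["a"] * 6
    for _ in range(30):
        m = int(rng.integers(1, 25))
        dos = rng.integers(0, 3, size=(m, 6)).astype(np.int8)
        dos[rng.random(size=dos.shape) < 0.1] = -1
        pos = np.sort(rng.choice(np.arange(1, 1001), size=m, replace=False))
        g = make_matrix(dos, pops, positions=pos)
        out = window_pi(g, "a", SweepParams(window=1000, step=1000), chrom_length=1000)
        assert out["pi"][0] * 1000 == pytest.approx(pairwise_pi_oracle(dos), abs=1e-12)


def test_pi_invariant_under_sample_reordering(rng):
    dos = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
    g1 = make_matrix(dos, ["a"] * 8)
    perm = rng.permutation(8)
    g2 = make_matrix(dos[:, perm], ["a"] * 8)
    p = SweepParams(window=200, step=200)
    assert window_pi(g1, "a", p, 200).equals(window_pi(g2, "a", p, 200))


# ---------------------------------------------------------------- FST


def test_fixed_difference_fst_one():
    g = make_matrix([[0, 0, 0, 2, 2, 2]], ["a", "a", "a", "b", "b", "b"])
    comp = wc_fst_components(g, ("a", "b"))
    fst = comp["a"][0] / (comp["a"][0] + comp["b"][0] + comp["c"][0])
    assert fst == pytest.approx(1.0, abs=1e-12)


def test_monomorphic_site_excluded():
    g = make_matrix([[1, 1, 1, 1], [0, 0, 0, 0]], ["a", "a", "b", "b"])
    comp = wc_fst_components(g, ("a", "b"))
    assert not comp["zero_denominator"][0]
    assert comp["zero_denominator"][1]


def test_random_sites_match_wc_oracle(rng):
    for _ in range(500):
        n1, n2 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
        d1 = rng.integers(0, 3, size=n1)
        d2 = rng.integers(0, 3, size=n2)
        g = make_matrix([list(d1) + list(d2)], ["a"] * n1 + ["b"] * n2)
        comp = wc_fst_components(g, ("a", "b"))
        a, b, c = wc_oracle(
            n1, d1.sum() / (2 * n1), (d1 == 1).sum() / n1,
            n2, d2.sum() / (2 * n2), (d2 == 1).sum() / n2,
        )
        if a + b + c == 0:
            assert comp["zero_denominator"][0]
        else:
            assert comp["a"][0] == pytest.approx(a, abs=1e-10)
            assert comp["b"][0] == pytest.approx(b, abs=1e-10)
            assert comp["c"][0] == pytest.approx(c, abs=1e-10)


def test_weighted_fst_equals_ratio_of_sums(rng):
    dos = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
    pops = ["a"] * 5 + ["b"] * 5
    g = make_matrix(dos, pops, positions=np.arange(1, 41) * 20)
    p = SweepParams(window=400, step=400)
    comp = wc_fst_components(g, ("a", "b"))
    win = window_fst_wc(g, ("a", "b"), p, chrom_length=800, site_components=comp)
    use = ~comp["zero_denominator"].to_numpy()
    in_w0 = (g.pos - 1 < 400) & use
    expected = comp["a"][in_w0].sum() / (comp["a"] + comp["b"] + comp["c"])[in_w0].sum()
    assert win["fst_weighted"][0] == expected  # exact recomputation from stored parts


def test_negative_fst_not_clamped():
    # equal frequencies, opposite homozygote arrangements -> negative estimate,
    # reported as computed
    g = make_matrix([[0, 2, 2, 0]], ["a", "a", "b", "b"])
    comp = wc_fst_components(g, ("a", "b"))
    ratio = comp["a"][0] / (comp["a"][0] + comp["b"][0] + comp["c"][0])
    assert ratio < 0


def test_fst_requires_two_pops():
    g = make_matrix([[1, 1]], ["a", "a"])
    with pytest.raises(ValueError):
        wc_fst_components(g, ("a",))


def test_fst_identical_pops_near_zero(rng):
    # neutral: one panmictic pool split arbitrarily into two labels
    m, n = 300, 40
    freqs = rng.uniform(0.1, 0.9, size=m)
    dos = rng.binomial(2, freqs[:, None], size=(m, n)).astype(np.int8)
    g = make_matrix(dos, ["a"] * 20 + ["b"] * 20, positions=np.arange(1, m + 1))
    p = SweepParams(window=300, step=300)
    win = window_fst_wc(g, ("a", "b"), p, chrom_length=300)
    assert abs(win["fst_weighted"][0]) < 0.02


# ---------------------------------------------------------------- Tajima's D


def test_tajima_constants_basic():
    k = tajima_constants(10)
    assert k.a1 == pytest.approx(sum(1 / i for i in range(1, 10)))
    assert all(v > 0 for v in (k.a1, k.a2, k.b1, k.b2))


def test_two_samples_d_zero():
    # n=2 alleles: one diploid, every segregating site het
    dos = [[1]] * 5
    g = make_matrix(dos, ["a"])
    out = window_tajima_d(g, "a", SweepParams(window=100, step=100), chrom_length=100)
    assert out["tajima_d"][0] == pytest.approx(0.0, abs=1e-12)


def test_no_segregating_sites_nan():
    g = make_matrix([[0, 0], [2, 2]], ["a", "a"])
    out = window_tajima_d(g, "a", SweepParams(window=100, step=100), chrom_length=100)
    assert math.isnan(out["tajima_d"][0])


@pytest.mark.parametrize("n_dip", [2, 4, 10, 25])
def test_tajima_matches_oracle(rng, n_dip):
    for _ in range(20):
        m = int(rng.integers(3, 30))
        dos = rng.integers(0, 3, size=(m, n_dip)).astype(np.int8)
        g = make_matrix(dos, ["a"] * n_dip, positions=np.arange(1, m + 1))
        out = window_tajima_d(g, "a", SweepParams(window=100, step=100), chrom_length=100)
        expected = tajima_oracle(dos)
        if math.isnan(expected):
            assert math.isnan(out["tajima_d"][0])
        else:
            assert out["tajima_d"][0] == pytest.approx(expected, abs=1e-10)


def test_d_invariant_under_allele_label_swap(rng):
    dos = rng.integers(0, 3, size=(15, 8)).astype(np.int8)
    g1 = make_matrix(dos, ["a"] * 8)
    g2 = make_matrix(2 - dos, ["a"] * 8)
    p = SweepParams(window=200, step=200)
    d1 = window_tajima_d(g1, "a", p, 200)["tajima_d"][0]
    d2 = window_tajima_d(g2, "a", p, 200)["tajima_d"][0]
    assert d1 == pytest.approx(d2, abs=1e-12)


# ---------------------------------------------------------------- ln-ratio


def _pi_df(vals, n_sites=10, window=100):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(len(vals)) * window,
            "end": (np.arange(len(vals)) + 1) * window,
            "n_sites": n_sites,
            "pi": vals,
        }
    )


def test_ln_ratio_equal_zero():
    out = pi_ln_ratio(_pi_df([0.01]), _pi_df([0.01]))
    assert out["pi_ln_ratio"][0] == pytest.approx(0.0)


def test_ln_ratio_e_squared():
    out = pi_ln_ratio(_pi_df([0.02 * math.e**2]), _pi_df([0.02]))
    assert out["pi_ln_ratio"][0] == pytest.approx(2.0, abs=1e-12)


def test_ln_ratio_nan_rules():
    out = pi_ln_ratio(_pi_df([0.01, 0.01]), _pi_df([0.0, 0.01]))
    assert math.isnan(out["pi_ln_ratio"][0])
    out2 = pi_ln_ratio(_pi_df([0.01], n_sites=0), _pi_df([0.01]), min_sites=1)
    assert math.isnan(out2["pi_ln_ratio"][0])


def test_ln_ratio_matches_recompute(rng):
    w = rng.uniform(0.001, 0.05, size=50)
    d = rng.uniform(0.001, 0.05, size=50)
    out = pi_ln_ratio(_pi_df(w), _pi_df(d))
    assert np.allclose(out["pi_ln_ratio"], np.log(w / d))


def test_ln_ratio_grid_mismatch():
    with pytest.raises(ValueError, match="grid"):
        pi_ln_ratio(_pi_df([0.01]), _pi_df([0.01, 0.02]))


# ---------------------------------------------------------------- sweeps


def _fst_df(vals, window=100):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(len(vals)) * window,
            "end": (np.arange(len(vals)) + 1) * window,
            "n_sites": 10,
            "fst_weighted": vals,
            "fst_mean": vals,
        }
    )


def _ln_df(vals, window=100):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(len(vals)) * window,
            "end": (np.arange(len(vals)) + 1) * window,
            "pi_ln_ratio": vals,
        }
    )


def test_select_sweeps_none_pass():
    fst = _fst_df([0.1] * 99 + [0.9])
    ln = _ln_df([2.0] + [0.1] * 99)  # dual outliers never coincide
    assert select_sweeps(fst, ln, SweepParams(quantile=0.99)) == []


def test_select_sweeps_merging_and_thresholds(rng):
    vals_f = list(rng.uniform(0, 0.2, size=200))
    vals_l = list(rng.uniform(-0.5, 0.5, size=200))
    for i in (50, 51, 52, 120):
        vals_f[i] = 0.9
        vals_l[i] = 3.0
    regions = select_sweeps(_fst_df(vals_f), _ln_df(vals_l), SweepParams(quantile=0.97))
    assert [(r.start, r.end) for r in regions] == [(5000, 5300), (12000, 12100)]
    # every member window exceeds both thresholds
    tf = nearest_rank_above_threshold(np.array(vals_f), 0.97)
    tl = nearest_rank_above_threshold(np.array(vals_l), 0.97)
    for r in regions:
        for w in r.window_indices:
            assert vals_f[w] >= tf and vals_l[w] >= tl


def test_select_sweeps_constant_tracks_tie_behavior():
    fst = _fst_df([0.5] * 50)
    ln = _ln_df([1.0] * 50)
    regions = select_sweeps(fst, ln, SweepParams(quantile=0.99))
    # documented: threshold equals the constant, >= makes all windows outliers
    assert len(regions) == 1
    assert regions[0].n_windows == 50


def test_select_sweeps_all_nan_error():
    fst = _fst_df([np.nan] * 10)
    ln = _ln_df([np.nan] * 10)
    with pytest.raises(ValueError):
        select_sweeps(fst, ln, SweepParams())


def test_merge_idempotent(rng):
    vals_f = list(rng.uniform(0, 0.2, size=100))
    vals_l = list(rng.uniform(-0.5, 0.5, size=100))
    for i in (10, 11, 40):
        vals_f[i] = 0.9
        vals_l[i] = 3.0
    p = SweepParams(quantile=0.95)
    r1 = select_sweeps(_fst_df(vals_f), _ln_df(vals_l), p)
    r2 = select_sweeps(_fst_df(vals_f), _ln_df(vals_l), p)
    assert [(a.start, a.end) for a in r1] == [(b.start, b.end) for b in r2]


# ---------------------------------------------------------------- gene overlap


GFF = """\
##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1
chr1\tsrc\tgene\t501\t600\t.\t-\t.\tID=g2
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=m1;Parent=g1
chr1\tsrc\tgene\t301\t400\t.\t+\t.\tID=g3
chr2\tsrc\tgene\t101\t200\t.\t+\t.\tID=g4
chr1\tsrc\tgene\t1001\t1100\t.\t+\t.\tID=g5
"""


def test_overlap_genes_toy(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(GFF)
    from xykit.popgen import SweepRegion

    regions = [SweepRegion("chr1", 150, 350, [], 0.0, 0.0),
               SweepRegion("chr1", 600, 1000, [], 0.0, 0.0)]
    overlap_genes(regions, gff)
    assert regions[0].genes == ["g1", "g3"]
    # g2 spans [500,600): abuts region start 600 -> zero overlap, excluded;
    # g5 starts at 0-based 1000, region ends at 1000 -> excluded
    assert regions[1].genes == []


def test_gene_nested_inside_region(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(GFF)
    from xykit.popgen import SweepRegion

    regions = [SweepRegion("chr1", 0, 5000, [], 0.0, 0.0)]
    overlap_genes(regions, gff)
    assert regions[0].genes == ["g1", "g2", "g3", "g5"]


def test_malformed_gff_line_number(tmp_path):
    gff = tmp_path / "bad.gff3"
    gff.write_text("chr1\tsrc\tgene\t1\t100\t.\t+\t.\n")  # 8 columns
    from xykit.popgen import SweepRegion

    with pytest.raises(ValueError, match=":1:"):
        overlap_genes([SweepRegion("chr1", 0, 10, [], 0.0, 0.0)], gff)


def test_allele_pattern_matrix(rng):
    dos = np.array([[2, 2, 2, 0], [1, 0, 1, 2], [0, 0, 0, 0]], dtype=np.int8)
    g = make_matrix(dos, ["w", "w", "d", "d"])
    df = allele_pattern_matrix(g, "w", maf_floor=0.05)
    # sites 1 and 3 are monomorphic in w (maf 0) -> dropped; at site 2 the
    # major w allele is REF so coding equals the dosages
    assert df["pos"].tolist() == [20]
    assert df.iloc[0][["s0", "s1", "s2", "s3"]].tolist() == [1, 0, 1, 2]
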