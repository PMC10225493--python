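import numpy as np
import pytest

from xykit._util import revcomp
from xykit.io import write_manifest
from xykit.readset import ReadSet
from xykit.sdr import (
    Placement,
    ReferenceIndex,
    WindowTrack,
    call_sdr,
    coverage_ratio,
    deduplicate,
    place_reads,
    sex_variant_density,
    window_depth,
)
from xykit.sim import ReadSimParams, SimGenomeParams, simulate_reads, simulate_xy_genome


@pytest.fixture(scope="module")
def pair():
    p = SimGenomeParams(chrom_lengths=(60_000, 30_000), sdr_interval=(20_000, 30_000),
                        msr_length=4_000, sdr_divergence=0.05, seed=21)
    return simulate_xy_genome(p)


# ---------------------------------------------------------------- placement


def test_error_free_reads_place_at_origin(pair):
    g, _ = pair
    rs = simulate_reads(g, ReadSimParams(n_males=1, n_females=0, coverage=1,
                                         read_length=80, error_rate=0.0, seed=2))["M1"]
    index = ReferenceIndex(g.male_assembly)
    placements = place_reads(rs, index, dedup=False)
    assert placements  # most reads place
    by_id = {p.read_id: p for p in placements}
    checked = 0
    for rid, p in by_id.items():
        sample, hap, chrom, start, strand, _ = rid.split("|")
        if hap == "Y" or chrom != g.sex_chrom:
            # coordinates on the male assembly match the encoded origin
            assert (p.chrom, p.start, p.strand) == (chrom, int(start), strand)
            checked += 1
    assert checked > 50


def test_y_insertion_read_unplaced_on_female_assembly(pair):
    g, truth = pair
    chrom, ms, me = truth.msr
    read = g.y[chrom][ms + 100 : ms + 200]
    placements = place_reads(ReadSet.from_strings([read]), ReferenceIndex(g.female_assembly))
    assert placements == []


def test_duplicate_placements_collapse():
    dups = [Placement("a", "chr1", 5, "+"), Placement("b", "chr1", 5, "+"),
            Placement("c", "chr1", 5, "-")]
    out = deduplicate(dups)
    assert [(p.read_id) for p in out] == ["a", "c"]


def test_multi_hit_seed_discarded():
    ref = {"chr1": "ACGTACGTACGT" + "AAGGTTCCAAGC" * 3 + "TTGCAGGA" * 4}
    # a read whose seed occurs twice in the reference is discarded
    rep = "AAGGTTCCAAGC" * 2
    idx = ReferenceIndex(ref, seed_length=8)
    assert place_reads(ReadSet.from_strings([rep[:20]]), idx) == []


def test_reverse_strand_placement(pair):
    g, _ = pair
    frag = g.male_assembly["chr2"][1000:1080]
    placements = place_reads(ReadSet.from_strings([revcomp(frag)]), ReferenceIndex(g.male_assembly))
    assert len(placements) == 1
    assert (placements[0].chrom, placements[0].start, placements[0].strand) == ("chr2", 1000, "-")


def test_max_mismatch(pair):
    g, _ = pair
    frag = list(g.male_assembly["chr2"][2000:2080])
    for pos in (40, 50, 60):
        frag[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[pos]]
    read = "".join(frag)
    idx = ReferenceIndex(g.male_assembly)
    assert place_reads(ReadSet.from_strings([read]), idx, max_mismatch=2) == []
    assert len(place_reads(ReadSet.from_strings([read]), idx, max_mismatch=3)) == 1


# ---------------------------------------------------------------- external mode


def _write_sam(path, sorted_order=True):
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate" if sorted_order else "unsorted"},
              "SQ": [{"LN": 10_000, "SN": "chr1"}]}
    recs = []
    for name, pos, mapq, flag in [("r1", 100, 60, 0), ("r2", 100, 60, 0), ("r3", 200, 5, 0),
                                  ("r4", 300, 60, 16), ("r5", 400, 60, 256)]:
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = "ACGT" * 10
        a.reference_id = 0
        a.reference_start = pos
        a.mapping_quality = mapq
        a.flag = flag
        a.cigarstring = "40M"
        recs.append(a)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in recs:
            fh.write(a)


def test_external_mode_filters(tmp_path):
    sam = tmp_path / "aln.sam"
    _write_sam(sam)
    placements = place_reads(None, None, mode="external", sam_path=sam, min_mapq=20)
    # r2 is a positional duplicate of r1; r3 fails MAPQ; r5 is secondary
    assert [(p.read_id, p.start, p.strand) for p in placements] == [("r1", 100, "+"), ("r4", 300, "-")]


def test_external_mode_requires_sorted(tmp_path):
    sam = tmp_path / "unsorted.sam"
    _write_sam(sam, sorted_order=False)
    with pytest.raises(ValueError, match="sorted"):
        place_reads(None, None, mode="external", sam_path=sam)


# ---------------------------------------------------------------- window depth


def test_zero_placements_zero_track():
    track = window_depth([], {"chr1": 1000}, 100)
    assert track.counts["chr1"].sum() == 0
    assert track.total_placements == 0


def test_single_placement_normalization():
    lengths = {"chr1": 1000}
    track = window_depth([Placement("r", "chr1", 310, "+")], lengths, 100)
    assert track.counts["chr1"][3] == 1
    assert track.norm["chr1"][3] == 1_000_000.0
    assert track.norm["chr1"].sum() == 1_000_000.0


def test_depth_matches_naive_binning(rng):
    lengths = {"chr1": 50_000, "chr2": 20_000}
    placements = []
    for i in range(10_000):
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        placements.append(Placement(f"r{i}", chrom, int(rng.integers(0, lengths[chrom])), "+"))
    track = window_depth(placements, lengths, 1000)
    for chrom in lengths:
        expected = np.zeros(lengths[chrom] // 1000, dtype=int)
        for p in placements:
            if p.chrom == chrom:
                expected[p.start // 1000] += 1
        assert track.counts[chrom].tolist() == expected.tolist()
    # conservation
    assert sum(v.sum() for v in track.counts.values()) == len(placements)


def test_placement_beyond_end_errors():
    with pytest.raises(ValueError, match="beyond"):
        window_depth([Placement("r", "chr1", 1200, "+")], {"chr1": 1000}, 100)


def test_partial_final_window_flag():
    track = window_depth([], {"chr1": 1050}, 100)
    assert track.partial_final_window("chr1")
    assert track.counts["chr1"].size == 11
    assert track.window_bounds("chr1")[-1].tolist() == [1000, 1050]


# ---------------------------------------------------------------- call_sdr


def _track(counts_by_chrom, window=100, lengths=None):
    lengths = lengths or {c: len(v) * window for c, v in counts_by_chrom.items()}
    placements = []
    for chrom, counts in counts_by_chrom.items():
        for w, n in enumerate(counts):
            placements.extend(
                Placement(f"{chrom}.{w}.{i}", chrom, w * window + i, "+") for i in range(n)
            )
    return window_depth(placements, lengths, window)


def test_all_zero_male_track_no_regions():
    m = _track({"chr1": [0] * 20})
    f = _track({"chr1": [0] * 20})
    assert call_sdr(m, f) == []


def test_two_clusters_beyond_merge_gap():
    counts = [0] * 30
    counts[5] = counts[6] = 50
    counts[12] = counts[13] = 60  # gap of 5 windows > merge_gap+1
    m = _track({"chr1": counts})
    f = _track({"chr1": [0] * 30})
    regions = call_sdr(m, f, merge_gap=2, min_windows=2)
    assert len(regions) == 2
    assert regions[0].total_reads == 120  # ranked by supporting reads


def test_min_windows_filter():
    counts = [0] * 30
    counts[5] = 50
    m = _track({"chr1": counts})
    f = _track({"chr1": [0] * 30})
    assert call_sdr(m, f, min_windows=2) == []
    assert len(call_sdr(m, f, min_windows=1)) == 1


def test_call_invariant_to_chromosome_order():
    counts = {"chr1": [0] * 10, "chr2": [0, 0, 40, 45, 0, 0, 0, 0, 0, 0]}
    m1 = _track(dict(sorted(counts.items())))
    m2 = _track(dict(sorted(counts.items(), reverse=True)))
    f = _track({c: [0] * 10 for c in counts})
    r1 = call_sdr(m1, f)
    r2 = call_sdr(m2, f)
    assert [(r.chrom, r.start, r.end) for r in r1] == [(r.chrom, r.start, r.end) for r in r2]


def test_grid_mismatch_error():
    m = _track({"chr1": [0] * 10}, window=100)
    f = _track({"chr1": [0] * 5}, window=200)
    with pytest.raises(ValueError, match="grid"):
        call_sdr(m, f)


# ---------------------------------------------------------------- coverage ratio


def test_ratio_identical_tracks_zero():
    m = _track({"chr1": [3, 1, 4, 1, 5]})
    r = coverage_ratio(m, m, pseudocount=1.0)
    assert np.allclose(r["chr1"], 0.0)


def test_ratio_hemizygous_window():
    m = _track({"chr1": [10, 0]})
    f = _track({"chr1": [0, 10]})
    r = coverage_ratio(m, f, pseudocount=1.0)
    assert r["chr1"][0] == np.log2((m.norm["chr1"][0] + 1) / 1.0)
    assert r["chr1"][0] > 0


def test_ratio_matches_formula(rng):
    m = _track({"chr1": rng.integers(0, 30, size=12).tolist()})
    f = _track({"chr1": rng.integers(0, 30, size=12).tolist()})
    c = 2.5
    r = coverage_ratio(m, f, pseudocount=c)
    expected = np.log2((m.norm["chr1"] + c) / (f.norm["chr1"] + c))
    assert np.allclose(r["chr1"], expected)


# ---------------------------------------------------------------- variant density


VCF_BODY = """\
chr1\t50\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\t0/0
chr1\t150\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/0
chr1\t160\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\t0/1
chr1\t250\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\t./.
chr2\t10\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0\t0/0
chr2\t20\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1\t0/0
"""


def _write_vcf(path):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=300>\n##contig=<ID=chr2,length=100>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tM1\tM2\tF1\tF2\n"
    )
    path.write_text(header + VCF_BODY)


def test_variant_density_hand_enumeration(tmp_path):
    vcf = tmp_path / "toy.vcf"
    _write_vcf(vcf)
    labels = {"M1": "male", "M2": "male", "F1": "female", "F2": "female"}
    track = sex_variant_density(vcf, labels, window=100)
    # window 0 of chr1: SNP at pos 50, both males het -> mean 1.0; females 0
    assert track.het_snp["male"]["chr1"].tolist() == [1.0, 0.0, 1.0]
    assert track.het_snp["female"]["chr1"].tolist() == [0.0, 0.0, 0.0]
    # indels at 150 (male: het+hom -> mean 0.5) and 160 (female mean 1.0)
    assert track.het_indel["male"]["chr1"].tolist() == [0.0, 0.5, 0.0]
    assert track.het_indel["female"]["chr1"].tolist() == [0.0, 1.0, 0.0]
    # male-specific: chr1:50 (het in all males, hom-ref females) and chr2:10;
    # chr1:150 male-specific indel; chr1:250 has a missing female -> still counted
    assert track.male_specific_snp["chr1"].tolist() == [1.0, 0.0, 1.0]
    assert track.male_specific_indel["chr1"].tolist() == [0.0, 1.0, 0.0]
    assert track.male_specific_snp["chr2"].tolist() == [1.0]


def test_variant_density_empty_vcf(tmp_path):
    vcf = tmp_path / "empty.vcf"
    header = (
        "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=300>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tM1\tF1\n"
    )
    vcf.write_text(header)
    track = sex_variant_density(vcf, {"M1": "male", "F1": "female"}, window=100)
    assert all(v.sum() == 0 for v in track.male_specific_snp.values())


def test_variant_density_missing_sample_error(tmp_path):
    vcf = tmp_path / "toy.vcf"
    _write_vcf(vcf)
    with pytest.raises(ValueError, match="missing"):
        sex_variant_density(vcf, {"M1": "male", "F1": "female", "ZZ": "male"}, window=100)
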