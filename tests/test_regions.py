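import numpy as np
import pytest

from svpopgen.regions import (
    OverlapRule,
    breakpoint_density,
    breakpoint_positions,
    candidate_enhancer_count,
    enhancer_candidates,
    hotspot_detect,
    novel_del_dup_total,
    novel_svs,
    overlap_match,
    peak_sv_classify,
    qtl_enrichment,
    sliding_windows,
    sv_supported_enhancers,
    telomere_enrichment,
)
from svpopgen.simulate import (
    HotspotCluster,
    PopulationSpec,
    Scenario,
    simulate_cohort,
)
from svpopgen.types import (
    GeneModel,
    Genome,
    GenomicInterval,
    IntervalSet,
    QtlRecord,
    SvRecord,
    SvSet,
)

from conftest import make_meta, make_svset


def _one_sv_set(records):
    geno = np.ones((1, len(records)), dtype=np.int8)
    return SvSet(records, geno, ["s1"])


# ---------------------------------------------------------------------------
# density


def test_window_tiling_covers_positions_twice():
    genome = Genome({"chr1": 10_000_000})
    wins = sliding_windows(genome, 1_000_000, 500_000)
    # every interior position is covered by exactly window/step = 2 windows
    for pos in (1_700_000, 5_000_000, 9_400_000):
        n_cover = ((wins["start"] <= pos) & (pos < wins["start"] + 1_000_000)).sum()
        assert n_cover == 2


def test_del_breakpoints_land_in_both_overlapping_windows():
    rec = SvRecord("d1", "chr1", 2_300_001, 2_400_000, "DEL", 100_000)
    svset = _one_sv_set([rec])
    genome = Genome({"chr1": 10_000_000})
    dens = breakpoint_density(svset, genome)
    hit = dens[dens["count"] > 0]
    # start 2.3 Mb lies in [1.5,2.5) and [2.0,3.0); end 2.4 Mb likewise
    assert set(zip(hit["start"], hit["count"])) == {(1_500_000, 2), (2_000_000, 2)}


def test_empty_sv_set_all_zero_density():
    svset = SvSet([], np.empty((1, 0), dtype=np.int8), ["s1"])
    dens = breakpoint_density(svset, Genome({"chr1": 5_000_000}))
    assert (dens["count"] == 0).all()


def test_density_matches_brute_force_scan():
    sc = Scenario(
        genome=[("chr1", 10_000_000)],
        n_loci=100,
        populations=[PopulationSpec("p", "native", "sheep", 5, 0.1)],
        seed=1,
    )
    svset, _meta, _ = simulate_cohort(sc)
    genome = Genome({"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000})
    dens = breakpoint_density(svset, genome)
    pts = breakpoint_positions(svset)
    for row in dens.itertuples():
        expected = sum(
            1 for c, p in pts if c == row.chrom and row.start <= p < row.start + 1_000_000
        )
        assert row.count == expected


def test_unknown_chromosome_is_an_error():
    rec = SvRecord("d1", "chrZ", 100, 200, "DEL", 101)
    with pytest.raises(ValueError, match="chrZ"):
        breakpoint_density(_one_sv_set([rec]), Genome({"chr1": 1_000_000}))


# ---------------------------------------------------------------------------
# hotspots


def test_hotspot_rank_arithmetic_top_window():
    import pandas as pd

    dens = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(10) * 500_000,
         "end": np.arange(10) * 500_000 + 1_000_000, "count": np.arange(9, -1, -1)}
    )
    hs = hotspot_detect(dens, top_fraction=0.10)
    assert len(hs.windows) == 1
    assert hs.windows["count"].iloc[0] == 9


def test_adjacent_hotspot_windows_merge():
    import pandas as pd

    dens = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(20) * 500_000,
            "end": np.arange(20) * 500_000 + 1_000_000,
            "count": [50, 49] + [0] * 18,
        }
    )
    hs = hotspot_detect(dens, top_fraction=0.10)
    assert hs.n_regions == 1
    region = hs.regions[0]
    assert (region.start, region.end) == (0, 1_500_000)
    # merged span equals the union of member windows
    assert hs.total_span == 1_500_000


def test_all_zero_density_is_an_error():
    import pandas as pd

    dens = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(12), "end": np.arange(12) + 1, "count": 0}
    )
    with pytest.raises(ValueError, match="zero"):
        hotspot_detect(dens)


def test_planted_clusters_fall_inside_merged_hotspots():
    hits = 0
    reps = 20
    for seed in range(reps):
        sc = Scenario(
            genome=[("chr1", 60_000_000), ("chr2", 50_000_000)],
            n_loci=1500,
            populations=[PopulationSpec("p", "native", "sheep", 5, 0.1)],
            hotspot_clusters=[
                HotspotCluster("chr1", 45_000_000, 250_000, 8.0),
                HotspotCluster("chr2", 10_000_000, 250_000, 8.0),
            ],
            seed=seed,
        )
        svset, _meta, _ = simulate_cohort(sc)
        genome = Genome(dict(sc.genome))
        hs = hotspot_detect(breakpoint_density(svset, genome))
        found = 0
        for cl in sc.hotspot_clusters:
            for g in hs.regions:
                if g.chrom == cl.chrom and g.start <= cl.center < g.end:
                    found += 1
                    break
        hits += found
    assert hits / (2 * reps) >= 0.95


# ---------------------------------------------------------------------------
# telomeres


def test_telomere_enrichment_extreme_case():
    rng = np.random.default_rng(0)
    pos = np.concatenate(
        [rng.integers(1, 4_900_000, size=100), rng.integers(45_100_000, 49_900_000, size=100)]
    )
    records = [
        SvRecord(f"d{i}", "chr1", int(p), int(p) + 99, "DEL", 100)
        for i, p in enumerate(pos)
    ]
    svset = _one_sv_set(records)
    res = telomere_enrichment(svset, Genome({"chr1": 50_000_000}))
    assert res["telomeric_breakpoints"] == res["total_breakpoints"]
    assert res["p_value"] < 1e-4
    assert res["statistic"] > 0


def test_telomere_type_one_error_calibrated_under_uniform_breakpoints():
    rng = np.random.default_rng(7)
    n_rej = 0
    reps = 300
    for _ in range(reps):
        pos = rng.integers(1, 49_999_000, size=150)
        records = [
            SvRecord(f"d{i}", "chr1", int(p), int(p) + 49, "DEL", 50)
            for i, p in enumerate(pos)
        ]
        res = telomere_enrichment(_one_sv_set(records), Genome({"chr1": 50_000_000}))
        if res["p_value"] < 0.05:
            n_rej += 1
    # two-sided test at alpha = 0.05: rejection rate ~5%, allow MC slack
    assert n_rej / reps < 0.10


def test_telomere_bin_counts_match_brute_force():
    records = [
        SvRecord("a", "chr1", 1_000_001, 1_000_100, "DEL", 100),
        SvRecord("b", "chr1", 25_000_001, 25_000_100, "DEL", 100),
        SvRecord("c", "chr1", 48_500_001, 48_500_100, "DEL", 100),
    ]
    svset = _one_sv_set(records)
    res = telomere_enrichment(svset, Genome({"chr1": 50_000_000}))
    assert res["telomeric_breakpoints"] == 4  # a (2 bps) + c (2 bps)
    assert res["total_breakpoints"] == 6
    assert res["n_telomeric_bins"] == 10
    assert res["n_other_bins"] == 40


# ---------------------------------------------------------------------------
# overlap matching


def test_overlap_rule_arithmetic_either_vs_both():
    a = GenomicInterval("chr1", 100, 200)
    b = GenomicInterval("chr1", 150, 350)
    either = OverlapRule(0.3, 0.3, mode="either")
    both = OverlapRule(0.3, 0.3, mode="both")
    assert either.matches(a, b)  # 50/100 = 0.5 >= 0.3
    assert not both.matches(a, b)  # 50/200 = 0.25 < 0.3


def test_overlap_match_equals_quadratic_brute_force():
    rng = np.random.default_rng(2)
    def rand_set(n, seed_offset):
        out = []
        for i in range(n):
            s = int(rng.integers(0, 1_000_000))
            out.append(
                GenomicInterval("chr1", s, s + int(rng.integers(50, 20_000)), name=f"x{i}")
            )
        return IntervalSet(out)

    A, B = rand_set(200, 0), rand_set(200, 1)
    rule = OverlapRule(0.5, 0.5, mode="either")
    pairs, unmatched = overlap_match(A, B, rule)
    got = {(a.name, b.start) for a, b in pairs}
    brute = {
        (a.name, b.start) for a in A for b in B if rule.matches(a, b)
    }
    assert got == brute
    brute_unmatched = {a.name for a in A} - {a.name for a, _ in pairs}
    assert {u.name for u in unmatched} == brute_unmatched


def test_overlap_match_symmetric_in_either_mode():
    rng = np.random.default_rng(9)
    ivs = [
        GenomicInterval("chr1", int(s), int(s) + int(l), name=str(i))
        for i, (s, l) in enumerate(
            zip(rng.integers(0, 100_000, 50), rng.integers(50, 5_000, 50))
        )
    ]
    A, B = IntervalSet(ivs[:25]), IntervalSet(ivs[25:])
    rule = OverlapRule(0.4, 0.4, mode="either")
    ab = {(a.name, b.name) for a, b in overlap_match(A, B, rule)[0]}
    ba = {(a.name, b.name) for b, a in overlap_match(B, A, rule)[0]}
    assert ab == ba


def test_novel_svs_identity_and_disjoint_catalogs():
    svset = make_svset([[1, 1], [1, 1], [1, 1]], spacing=50_000, length=1000)
    identical = IntervalSet([r.interval for r in svset.records])
    ids, table = novel_svs(svset, identical)
    assert ids == []
    far = IntervalSet([GenomicInterval("chr2", 1, 100)])
    ids2, table2 = novel_svs(svset, far)
    assert len(ids2) == 3
    assert table2["pct_novel"].iloc[0] == 100.0


def test_novel_planted_half_overlap_fixture():
    svset = make_svset([[1]] * 4, spacing=100_000, length=1000)
    # catalog matches the first two SVs reciprocally, misses the last two
    catalog = IntervalSet(
        [r.interval for r in svset.records[:2]]
        + [GenomicInterval("chr1", 900_000, 900_050)]
    )
    ids, table = novel_svs(svset, catalog)
    assert ids == [r.id for r in svset.records[2:]]
    n, pct = novel_del_dup_total(table)
    assert n == 2 and pct == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# QTL enrichment


def test_qtl_fold_enrichment_arithmetic():
    # toy genome 10 Mb, one 1-Mb QTL, 10 carried SVs of which 3 inside
    records = []
    for i in range(3):
        s = 1_000_001 + i * 100_000
        records.append(SvRecord(f"in{i}", "chr1", s, s + 999, "DEL", 1000))
    for i in range(7):
        s = 5_000_001 + i * 200_000
        records.append(SvRecord(f"out{i}", "chr1", s, s + 999, "DEL", 1000))
    geno = np.ones((1, 10), dtype=np.int8)
    svset = SvSet(records, geno, ["s1"])
    meta = make_meta({"s1": ("p", "native", "sheep")})
    qtls = [QtlRecord(GenomicInterval("chr1", 1_000_000, 2_000_000), "meat")]
    genome = Genome({"chr1": 10_000_000})
    table = qtl_enrichment(svset, meta, qtls, genome)
    row = table.iloc[0]
    assert row["observed"] == 3
    assert row["fold"] == pytest.approx(3.0)
    assert row["log2_fold"] == pytest.approx(np.log2(3.0))


def test_qtl_zero_observed_uses_flagged_pseudocount():
    records = [SvRecord("a", "chr1", 9_000_001, 9_001_000, "DEL", 1000)]
    svset = SvSet(records, np.ones((1, 1), dtype=np.int8), ["s1"])
    meta = make_meta({"s1": ("p", "native", "sheep")})
    qtls = [QtlRecord(GenomicInterval("chr1", 0, 1_000_000), "meat")]
    table = qtl_enrichment(svset, meta, qtls, Genome({"chr1": 10_000_000}))
    row = table.iloc[0]
    assert row["zero_observed"]
    assert row["log2_fold"] == pytest.approx(np.log2(0.5 / 0.1))


# ---------------------------------------------------------------------------
# peak classification


def test_peak_sv_boundary_is_strict_half():
    sv = SvRecord("s", "chr1", 1, 1000, "DEL", 1000)
    svset = SvSet([sv], np.ones((1, 1), dtype=np.int8), ["x"])
    peaks_499 = IntervalSet([GenomicInterval("chr1", 0, 499)])
    peaks_500 = IntervalSet([GenomicInterval("chr1", 0, 500)])
    assert not peak_sv_classify(svset, peaks_499)["peak_sv"].iloc[0]
    assert peak_sv_classify(svset, peaks_500)["peak_sv"].iloc[0]


def test_peak_overlap_accumulates_across_merged_peaks():
    sv = SvRecord("s", "chr1", 1, 1000, "DEL", 1000)
    svset = SvSet([sv], np.ones((1, 1), dtype=np.int8), ["x"])
    peaks = IntervalSet(
        [GenomicInterval("chr1", 0, 300), GenomicInterval("chr1", 600, 900)]
    )
    out = peak_sv_classify(svset, peaks)
    assert out["overlap_bp"].iloc[0] == 600
    assert out["peak_sv"].iloc[0]


def test_peak_partition_matches_brute_force(default_cohort):
    sc, svset, _meta, truth = default_cohort
    from svpopgen.simulate import default_annotation_fixtures

    genome = Genome(dict(sc.genome))
    _genes, _qtls, peaks = default_annotation_fixtures(genome, seed=truth.seed)
    merged = peaks.merge()
    out = peak_sv_classify(svset, merged)
    assert len(out) == svset.n_loci
    merged_list = merged.by_chrom()
    for row in out.sample(50, random_state=0).itertuples():
        rec = next(r for r in svset.records if r.id == row.sv_id)
        iv = rec.interval
        brute = sum(iv.overlap_len(g) for g in merged_list.get(iv.chrom, []))
        assert row.overlap_bp == brute
        assert row.peak_sv == (brute >= 0.5 * len(iv))


# ---------------------------------------------------------------------------
# enhancers


def _gene(chrom, start, end, strand, gid="g1"):
    return GeneModel(gid, chrom, start, end, strand, exons=((start, end),))


def test_promoter_peak_excluded_enhancer_kept():
    genes = [_gene("chr1", 10_000, 20_000, "+")]
    peaks = IntervalSet(
        [
            GenomicInterval("chr1", 9_500, 10_500, name="on_tss"),
            GenomicInterval("chr1", 40_000, 40_500, name="far"),
        ]
    )
    cands, proms = enhancer_candidates(peaks, genes)
    assert [p.name for p in proms] == ["on_tss"]
    assert [p.name for p in cands] == ["far"]
    assert candidate_enhancer_count(len(peaks), len(proms)) == 1


def test_minus_strand_tss_at_span_end():
    genes = [_gene("chr1", 10_000, 20_000, "-")]
    peaks = IntervalSet(
        [
            GenomicInterval("chr1", 19_500, 20_500, name="tss_minus"),
            GenomicInterval("chr1", 9_000, 9_500, name="tail"),
        ]
    )
    cands, proms = enhancer_candidates(peaks, genes)
    assert [p.name for p in proms] == ["tss_minus"]
    assert [p.name for p in cands] == ["tail"]


def test_sv_supported_enhancers_require_half_sv_length():
    genes = [_gene("chr1", 500_000, 510_000, "+")]
    peaks = IntervalSet(
        [
            GenomicInterval("chr1", 100_000, 101_000, name="hit"),
            GenomicInterval("chr1", 200_000, 200_100, name="small"),
        ]
    )
    cands, _ = enhancer_candidates(peaks, genes)
    records = [
        SvRecord("inpeak", "chr1", 100_101, 100_700, "DEL", 600),
        SvRecord("partial", "chr1", 200_051, 200_950, "DEL", 900),
    ]
    svset = SvSet(records, np.ones((1, 2), dtype=np.int8), ["x"])
    supported = sv_supported_enhancers(cands, svset)
    assert [g.name for g in supported] == ["hit"]
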