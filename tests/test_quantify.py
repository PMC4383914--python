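from __future__ import annotations

import random

import pytest

from apasites.io import GeneModel
from apasites.quantify import (
    annotate_site,
    build_usage_matrix,
    gene_expression,
    heterogeneity_profile,
    normalize_counts,
    usage_fractions,
)
from apasites.sites import CleavageCluster, PolyASite, call_polya_sites


def model_plus(gene="gA", tx="tA"):
    # exons [100,200)+[300,400), CDS [120,200)+[300,350): TTS 400,
    # 3'-UTR [350,400), 5'-UTR [100,120)
    return GeneModel(gene, tx, "chr1", "+",
                     ((100, 200), (300, 400)),
                     ((120, 200), (300, 350)))


class TestAnnotateSite:
    @pytest.mark.parametrize(
        "ref,category,gene",
        [
            (400, "known_TTS", "gA"),          # exactly at the TTS
            (420, "known_TTS", "gA"),          # within the 24-nt tolerance
            (360, "three_prime_utr", "gA"),    # in UTR, >24 nt from TTS
            (900, "downstream_1kb", "gA"),     # 500 nt past the TTS
            (1900, "intergenic", None),        # 1500 nt past the TTS
            (130, "internal_exon", "gA"),      # coding exon
            (250, "intron", "gA"),
            (105, "five_prime_utr", "gA"),
        ],
    )
    def test_category_precedence(self, ref, category, gene):
        ann = annotate_site(("chr1", "+", ref), [model_plus()])
        assert (ann.category, ann.gene_id) == (category, gene)

    def test_antisense_site_falls_through_to_intergenic(self):
        ann = annotate_site(("chr1", "-", 360), [model_plus()])
        assert ann.category == "intergenic" and ann.gene_id is None

    def test_minus_strand_downstream_goes_left(self):
        minus = GeneModel("gM", "tM", "chr1", "-", ((5000, 5400),))
        assert annotate_site(("chr1", "-", 4500), [minus]).category == \
            "downstream_1kb"
        assert annotate_site(("chr1", "-", 3900), [minus]).category == \
            "intergenic"

    def test_nearest_tts_wins_and_order_does_not_matter(self):
        far = GeneModel("gB", "tB", "chr1", "+", ((100, 800),))  # TTS 800
        models = [model_plus(), far]
        ref = 360  # in gA's UTR and inside gB's exon: UTR is more specific
        for order in (models, models[::-1]):
            ann = annotate_site(("chr1", "+", ref), order)
            assert (ann.category, ann.gene_id) == ("three_prime_utr", "gA")
        # both offer known_TTS at 410: gA TTS 400 (d=10) vs a gC TTS 420 (d=10)
        twin = GeneModel("gC", "tC", "chr1", "+", ((100, 420),))
        for order in ([model_plus(), twin], [twin, model_plus()]):
            ann = annotate_site(("chr1", "+", 410), order)
            assert ann.gene_id == "gA"  # tie on distance -> lexicographic

    def test_random_permutations_never_change_annotation(self):
        rng = random.Random(4)
        models = [model_plus(),
                  GeneModel("gB", "tB", "chr1", "+", ((500, 1200),)),
                  GeneModel("gM", "tM", "chr1", "-", ((200, 900),))]
        for ref in rng.sample(range(1, 2500), 60):
            baseline = annotate_site(("chr1", "+", ref), models)
            for _ in range(3):
                rng.shuffle(models)
                assert annotate_site(("chr1", "+", ref), models) == baseline


class TestNormalizeCounts:
    @pytest.mark.parametrize("raw,total,rpm", [(5, 2_000_000, 2.5),
                                               (0, 10, 0.0),
                                               (1_000_000, 1_000_000, 1e6)])
    def test_arithmetic(self, raw, total, rpm):
        assert normalize_counts(raw, total) == pytest.approx(rpm)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            normalize_counts(1, 0)


def _sites_for_matrix():
    """Two sites x three samples with hand-computed RPM (spreadsheet oracle).

    totals: s1 2e6, s2 1e6, s3 5e5
    site A raw: s1 3, s3 5  -> RPM 1.5, 0, 10.0
    site B raw: s1 1, s2 4, s3 2 -> RPM 0.5, 4.0, 4.0
    """
    totals = {"s1": 2_000_000, "s2": 1_000_000, "s3": 500_000}
    ca = CleavageCluster("c", "+", {100: 8},
                         {"s1": {100: 3}, "s3": {100: 5}})
    cb = CleavageCluster("c", "+", {500: 7},
                         {"s1": {500: 1}, "s2": {500: 4}, "s3": {500: 2}})
    sites = call_polya_sites([ca, cb], totals, min_pooled_rpm=0)
    return sites, totals


class TestUsageMatrix:
    def test_matches_hand_arithmetic(self):
        sites, _ = _sites_for_matrix()
        matrix = build_usage_matrix(sites, ["s1", "s2", "s3"])
        a, b = matrix.rpm.index
        assert list(matrix.rpm.loc[a]) == pytest.approx([1.5, 0.0, 10.0])
        assert list(matrix.rpm.loc[b]) == pytest.approx([0.5, 4.0, 4.0])

    def test_absent_sample_site_combination_is_zero(self):
        sites, _ = _sites_for_matrix()
        matrix = build_usage_matrix(sites, ["s1", "s2", "s3"])
        assert matrix.rpm.iloc[0]["s2"] == 0.0

    def test_single_site_equals_normalize_counts(self):
        cl = CleavageCluster("c", "+", {10: 7}, {"s1": {10: 7}})
        (site,) = call_polya_sites([cl], {"s1": 350_000}, 0)
        matrix = build_usage_matrix([site], ["s1"])
        assert matrix.rpm.iloc[0, 0] == pytest.approx(
            normalize_counts(7, 350_000))

    def test_sample_absent_from_manifest_is_error(self):
        sites, _ = _sites_for_matrix()
        with pytest.raises(KeyError):
            build_usage_matrix(sites, ["s1", "s2"])


def _annotated_matrix():
    sites, _ = _sites_for_matrix()
    for site in sites:
        site.annotation = type("A", (), {"gene_id": "gX", "category": "x"})()
    return build_usage_matrix(sites, ["s1", "s2", "s3"]), sites


class TestGeneLevel:
    def test_expression_is_sum_of_site_rpm(self):
        matrix, _ = _annotated_matrix()
        expr = gene_expression("gX", matrix)
        assert list(expr) == pytest.approx([2.0, 4.0, 14.0])

    def test_single_site_gene_expression_is_site_rpm(self):
        cl = CleavageCluster("c", "+", {10: 2}, {"s1": {10: 2}})
        (site,) = call_polya_sites([cl], {"s1": 1000}, 0)
        site.annotation = type("A", (), {"gene_id": "g", "category": "x"})()
        matrix = build_usage_matrix([site], ["s1"])
        assert gene_expression("g", matrix)["s1"] == site.rpm["s1"]

    def test_unknown_gene_is_error(self):
        matrix, _ = _annotated_matrix()
        with pytest.raises(KeyError):
            gene_expression("nope", matrix)

    def test_usage_fractions(self):
        matrix, _ = _annotated_matrix()
        fr = usage_fractions("gX", matrix, "s3")
        assert list(fr) == pytest.approx([10 / 14, 4 / 14])
        assert fr.sum() == pytest.approx(1.0)
        # s2 only has site B: single expressed site -> fraction {0, 1}
        assert list(usage_fractions("gX", matrix, "s2")) == \
            pytest.approx([0.0, 1.0])

    def test_zero_expression_reported_as_absent(self):
        cl = CleavageCluster("c", "+", {10: 1}, {"s1": {10: 1}})
        (site,) = call_polya_sites([cl], {"s1": 1000, "s2": 1000}, 0)
        site.annotation = type("A", (), {"gene_id": "g", "category": "x"})()
        matrix = build_usage_matrix([site], ["s1", "s2"])
        assert usage_fractions("g", matrix, "s2") is None


class TestHeterogeneityProfile:
    def test_relative_frequencies(self):
        cl = CleavageCluster("c", "+", {100: 3, 101: 1},
                             {"s1": {100: 3, 101: 1}})
        (site,) = call_polya_sites([cl], {"s1": 1000}, 0)
        profile = heterogeneity_profile(site)
        assert profile.frequencies == pytest.approx({100: 0.75, 101: 0.25})
        assert profile.reference_fraction == 0.75

    def test_single_position_cluster(self):
        cl = CleavageCluster("c", "-", {50: 4}, {"s1": {50: 4}})
        (site,) = call_polya_sites([cl], {"s1": 1000}, 0)
        profile = heterogeneity_profile(site)
        assert profile.frequencies == {50: 1.0}

    def test_frequencies_sum_to_one_and_mode_is_reference(self):
        rng = random.Random(6)
        for _ in range(20):
            counts = {p: rng.randint(1, 20)
                      for p in rng.sample(range(1000), rng.randint(1, 8))}
            cl = CleavageCluster("c", "+", counts, {"s1": counts})
            (site,) = call_polya_sites([cl], {"s1": 10}, 0)
            profile = heterogeneity_profile(site)
            assert sum(profile.frequencies.values()) == pytest.approx(1.0)
            assert profile.reference_fraction == max(
                profile.frequencies.values())
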