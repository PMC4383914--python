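from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apasites.io import Genome, reverse_complement
from apasites.preprocess import CleavageEvent
from apasites.sites import (
    CleavageCluster,
    call_polya_sites,
    cluster_events,
    downstream_window,
    find_signals,
    internal_priming_flag,
)

from conftest import make_window_genome
from oracles import internal_priming_oracle, union_find_clusters


# ------------------------------------------------------ internal priming

class TestInternalPrimingFlag:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("AAAAAAAAAAAAAGGGGGGG", True),   # 13 A's
            ("CAAAAAAAACCCCCCCCCCC", True),   # A8 run, only 8 A's total
            ("GAAAAGAAAGCCCCCCCCCC", True),   # G A{4+} G A{3+} G
            ("AAAAAACAAAAAACCCCCCC", False),  # exactly 12 A's, no pattern
        ],
    )
    def test_rule_examples(self, window, expected):
        genome, pos = make_window_genome(window)
        assert internal_priming_flag(genome, "chrW", "+", pos) is expected

    def test_minus_strand_window_is_reverse_complemented(self):
        window = "AAAAAAAAAAAAAGGGGGGG"
        # lay the window out so the minus-strand transcript reads it 5'->3'
        seq = "C" * 5 + reverse_complement(window) + "C" * 5
        genome = Genome({"c": seq})
        pos = 26  # 1-based; downstream on '-' is positions 6..25
        assert downstream_window(genome, "c", "-", pos) == window
        assert internal_priming_flag(genome, "c", "-", pos)

    def test_n_never_counts_as_a(self):
        genome, pos = make_window_genome("AANAAAAANAAAAANAAAAC")  # 16 A, 3 N
        # 16 A's > 12 still flags; but N breaks the A8 run check
        assert internal_priming_flag(genome, "chrW", "+", pos)
        genome2, pos2 = make_window_genome("AAANAAAACCCCCCCCCCCC")
        assert not internal_priming_flag(genome2, "chrW", "+", pos2)

    def test_truncated_window_at_chromosome_end(self):
        genome = Genome({"c": "CCCCCAAAAA"})
        # only 5 nt downstream available: 5 A's, no pattern -> not flagged
        assert not internal_priming_flag(genome, "c", "+", 5)
        # at the very last base the window is empty
        assert not internal_priming_flag(genome, "c", "+", 10)

    @given(st.text(alphabet="ACGT", min_size=20, max_size=20))
    @settings(max_examples=500, deadline=None, derandomize=True)
    def test_agrees_with_regex_count_oracle(self, window):
        genome, pos = make_window_genome(window)
        assert internal_priming_flag(genome, "chrW", "+", pos) == \
            internal_priming_oracle(window)


# ------------------------------------------------------------ clustering

def _events(positions, strand="+", chrom="c"):
    return [CleavageEvent(chrom, strand, p, f"r{i}")
            for i, p in enumerate(positions)]


class TestClusterEvents:
    def test_printed_trio_forms_one_cluster(self):
        clusters = cluster_events(_events([142767384, 142767390, 142767391]))
        assert len(clusters) == 1
        assert clusters[0].span == (142767384, 142767391)

    @pytest.mark.parametrize("second,n_clusters", [(124, 1), (125, 2)])
    def test_24nt_gap_boundary(self, second, n_clusters):
        assert len(cluster_events(_events([100, second]))) == n_clusters

    def test_opposite_strands_never_merge(self):
        events = _events([100, 110]) + _events([100, 110], strand="-")
        clusters = cluster_events(events)
        assert len(clusters) == 2
        assert {c.strand for c in clusters} == {"+", "-"}

    def test_order_independence(self):
        rng = random.Random(5)
        positions = [rng.randrange(10_000) for _ in range(200)]
        events = _events(positions)
        shuffled = events[:]
        rng.shuffle(shuffled)
        key = lambda cs: [(c.span, sorted(c.counts.items())) for c in cs]
        assert key(cluster_events(events)) == key(cluster_events(shuffled))

    def test_matches_union_find_oracle_on_random_instances(self):
        rng = random.Random(42)
        for _ in range(200):
            positions = [rng.randrange(2000) for _ in range(rng.randint(1, 60))]
            clusters = cluster_events(_events(positions))
            assert {frozenset(c.counts) for c in clusters} == \
                union_find_clusters(positions)

    def test_partition_and_gap_law(self):
        rng = random.Random(9)
        positions = [rng.randrange(5000) for _ in range(300)]
        clusters = cluster_events(_events(positions))
        assert sum(c.total for c in clusters) == len(positions)
        spans = sorted(c.span for c in clusters)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            assert lo - hi > 24


# ---------------------------------------------------------- site calling

def _cluster(counts, strand="+", sample="s1", chrom="c"):
    return CleavageCluster(chrom, strand, dict(counts), {sample: dict(counts)})


class TestCallPolyASites:
    def test_rpm_arithmetic_and_reference(self):
        (site,) = call_polya_sites([_cluster({100: 3, 105: 2})],
                                   {"s1": 1_000_000})
        assert site.pooled_rpm == pytest.approx(5.0)
        assert site.reference_pos == 100

    def test_below_two_normalized_reads_discarded(self):
        sites = call_polya_sites([_cluster({100: 1})], {"s1": 1_000_000})
        assert sites == []

    @pytest.mark.parametrize("strand,expected_ref", [("+", 105), ("-", 100)])
    def test_mode_tie_breaks_3prime_most(self, strand, expected_ref):
        (site,) = call_polya_sites([_cluster({100: 2, 105: 2}, strand=strand)],
                                   {"s1": 1000})
        assert site.reference_pos == expected_ref

    def test_zero_mapped_total_is_error(self):
        with pytest.raises(ValueError):
            call_polya_sites([_cluster({100: 3})], {"s1": 0})

    def test_reference_carries_maximal_count(self):
        rng = random.Random(3)
        clusters = [
            _cluster({rng.randrange(1000): rng.randint(1, 9) for _ in range(5)})
            for _ in range(30)
        ]
        for site in call_polya_sites(clusters, {"s1": 1000}, 0):
            assert site.cluster.counts[site.reference_pos] == \
                max(site.cluster.counts.values())

    def test_raising_threshold_never_adds_sites(self):
        rng = random.Random(8)
        clusters = [_cluster({rng.randrange(10_000): rng.randint(1, 5)})
                    for _ in range(40)]
        totals = {"s1": 500_000}
        counts = [len(call_polya_sites(clusters, totals, t))
                  for t in (0, 2, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)


# --------------------------------------------------------- signal search

class TestFindSignals:
    def _genome_with_hexamer_at(self, offset, ref=200, hexamer="AATAAA"):
        seq = list("C" * 400)
        start0 = ref - offset - 1  # hexamer start, 0-based, plus strand
        seq[start0 : start0 + 6] = hexamer
        return Genome({"c": "".join(seq)})

    def test_hexamer_16nt_upstream(self):
        genome = self._genome_with_hexamer_at(16)
        found = find_signals(genome, ("c", "+", 200))
        assert [(s.hexamer, s.offset) for s in found] == [("AATAAA", 16)]

    @pytest.mark.parametrize("offset,n_found", [(50, 1), (51, 0), (6, 1)])
    def test_window_boundary(self, offset, n_found):
        genome = self._genome_with_hexamer_at(offset)
        assert len(find_signals(genome, ("c", "+", 200))) == n_found

    def test_minus_strand_site(self):
        # transcript-strand hexamer upstream of a minus-strand site
        seq = list("G" * 400)
        ref = 200
        offset = 20
        seq[ref + offset - 6 : ref + offset] = reverse_complement("AATAAA")
        genome = Genome({"c": "".join(seq)})
        found = find_signals(genome, ("c", "-", ref))
        assert [(s.hexamer, s.offset) for s in found] == [("AATAAA", 20)]

    def test_no_signal_is_permitted(self):
        genome = Genome({"c": "C" * 400})
        assert find_signals(genome, ("c", "+", 200)) == []

    def test_window_truncated_at_chromosome_start(self):
        genome = self._genome_with_hexamer_at(10, ref=20)
        found = find_signals(genome, ("c", "+", 20))
        assert [(s.hexamer, s.offset) for s in found] == [("AATAAA", 10)]

    def test_empty_signal_set_is_error(self):
        genome = Genome({"c": "C" * 100})
        with pytest.raises(ValueError):
            find_signals(genome, ("c", "+", 50), signal_set=())
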