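import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sedm.intervals import (
    ChromSizes,
    GenomicInterval,
    IntervalSet,
    coverage_in_windows,
    distance_to_interval,
    jaccard,
    net_intersection_length,
    normalize,
    projection_overlap_stats,
    tile_genome,
)
from oracles import coverage_length_oracle, jaccard_oracle, merge_oracle


def iset(*pairs, chrom="chr1"):
    return IntervalSet([GenomicInterval(chrom, s, e) for s, e in pairs])


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError, match="malformed"):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length() == 100
        assert iv.midpoint() == 150


class TestNormalize:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(100, 160), (150, 200)], [(100, 200)]),  # overlapping merge
            ([(0, 50), (100, 150)], [(0, 50), (100, 150)]),  # already disjoint
            ([(100, 150), (150, 200)], [(100, 200)]),  # touching merge
        ],
    )
    def test_merge_semantics(self, pairs, expected):
        out = normalize(iset(*pairs))
        assert [(iv.start, iv.end) for iv in out] == expected

    def test_idempotent_and_coverage_conserving(self, rng):
        for _ in range(200):
            n = rng.integers(1, 10)
            starts = rng.integers(0, 400, n)
            lens = rng.integers(1, 100, n)
            s = IntervalSet(
                [GenomicInterval("c", int(a), int(a + l)) for a, l in zip(starts, lens)]
            )
            once = normalize(s)
            assert once.is_normalized()
            assert normalize(once) == once
            assert once.total_length() == s.coverage()
            assert [(iv.start, iv.end) for iv in once] == merge_oracle(
                [(iv.start, iv.end) for iv in s]
            )


class TestNetIntersectionLength:
    @pytest.mark.parametrize(
        "region,peaks,expected",
        [
            ((100, 200), [(150, 250)], 50),
            ((100, 200), [(90, 120), (180, 300)], 40),
            ((100, 200), [(100, 160), (150, 200)], 100),  # overlapping peaks count once
        ],
    )
    def test_examples(self, region, peaks, expected):
        r = GenomicInterval("chr1", *region)
        assert net_intersection_length(r, iset(*peaks)) == expected

    def test_absent_chromosome_is_zero(self):
        r = GenomicInterval("chr2", 0, 100)
        assert net_intersection_length(r, iset((0, 50))) == 0

    def test_matches_per_base_oracle(self, rng):
        for _ in range(300):
            rs = int(rng.integers(0, 300))
            region = GenomicInterval("chr1", rs, rs + int(rng.integers(1, 500)))
            k = int(rng.integers(0, 10))
            pairs = []
            for _ in range(k):
                s = int(rng.integers(0, 700))
                pairs.append((s, s + int(rng.integers(1, 120))))
            got = net_intersection_length(region, iset(*pairs))
            assert got == coverage_length_oracle((region.start, region.end), pairs)

    def test_vectorized_windows_agree_with_scalar(self, rng):
        pairs = [(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 5000, 30), rng.integers(1, 300, 30))]
        peaks = iset(*pairs)
        ws = rng.integers(0, 5000, 50)
        we = ws + rng.integers(1, 400, 50)
        vec = coverage_in_windows(peaks, "chr1", ws, we)
        for s, e, v in zip(ws, we, vec):
            assert v == net_intersection_length(GenomicInterval("chr1", int(s), int(e)), peaks)


class TestTileGenome:
    def test_truncated_final_tile(self):
        tiles = tile_genome(ChromSizes({"c": 250}), width=100)
        assert [(iv.start, iv.end) for iv in tiles] == [(0, 100), (100, 200), (200, 250)]

    def test_exact_fit(self):
        tiles = tile_genome(ChromSizes({"c": 100}), width=100)
        assert [(iv.start, iv.end) for iv in tiles] == [(0, 100)]

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            tile_genome(ChromSizes({"c": 0}), width=100)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            tile_genome(ChromSizes({"c": 100}), width=0)

    def test_tiles_partition_genome(self, rng):
        for _ in range(50):
            sizes = ChromSizes(
                {f"c{i}": int(rng.integers(1, 1000)) for i in range(int(rng.integers(1, 4)))}
            )
            width = int(rng.integers(1, 150))
            tiles = tile_genome(sizes, width=width)
            assert tiles.total_length() == sizes.genome_length()
            assert tiles.coverage() == sizes.genome_length()  # no overlap anywhere


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([(0, 100)], [(0, 100)], 1.0),
            ([(0, 100)], [(200, 300)], 0.0),
            ([(0, 100)], [(50, 150)], 50 / 150),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard(iset(*a), iset(*b)) == pytest.approx(expected)

    def test_empty_sets_define_zero(self):
        assert jaccard(IntervalSet(), IntervalSet()) == 0.0

    def test_symmetric_and_self_unit(self, rng):
        for _ in range(100):
            a = iset(*[(int(s), int(s) + int(l)) for s, l in
                       zip(rng.integers(0, 500, 5), rng.integers(1, 100, 5))])
            b = iset(*[(int(s), int(s) + int(l)) for s, l in
                       zip(rng.integers(0, 500, 5), rng.integers(1, 100, 5))])
            assert jaccard(a, b) == pytest.approx(jaccard(b, a))
            assert jaccard(a, a) == pytest.approx(1.0)
            assert jaccard(a, b) == pytest.approx(
                jaccard_oracle(
                    [(iv.start, iv.end) for iv in a], [(iv.start, iv.end) for iv in b]
                )
            )


class TestDistance:
    @pytest.mark.parametrize(
        "pos,region,expected",
        [
            (150, (100, 200), 0),
            (50, (100, 200), 50),
            (1_500_000, (2_000_000, 2_010_000), 500_000),
        ],
    )
    def test_examples(self, pos, region, expected):
        assert distance_to_interval(pos, GenomicInterval("chr1", *region)) == expected

    def test_cross_chromosome_is_infinite(self):
        r = GenomicInterval("chr2", 100, 200)
        assert distance_to_interval(150, r, chrom="chr1") == math.inf

    def test_right_side_measures_to_last_base(self):
        # region [100, 200): last covered base is 199
        assert distance_to_interval(210, GenomicInterval("c", 100, 200)) == 11


class TestProjectionOverlap:
    def test_arithmetic_example(self):
        sizes = ChromSizes({"c": 1000})
        reference = iset((0, 100))
        # 10 query points, 3 midpoints inside the reference
        query = iset(*[(i, i + 1) for i in [10, 50, 90, 150, 250, 350, 450, 550, 650, 750]])
        stats = projection_overlap_stats(query, reference, sizes)
        assert stats.observed == 3
        assert stats.expected == pytest.approx(1.0)
        assert stats.ratio == pytest.approx(3.0)
        # binomial upper tail P(X >= 3 | n=10, p=0.1)
        assert stats.p_value == pytest.approx(0.0702, abs=1e-4)

    def test_whole_genome_reference(self):
        sizes = ChromSizes({"c": 1000})
        query = iset((10, 20), (500, 600))
        stats = projection_overlap_stats(query, iset((0, 1000)), sizes)
        assert stats.ratio == pytest.approx(1.0)
        assert stats.p_value == pytest.approx(1.0)

    def test_empty_query_reports_missing_ratio(self):
        stats = projection_overlap_stats(
            IntervalSet(), iset((0, 100)), ChromSizes({"c": 1000})
        )
        assert stats.observed == 0
        assert stats.ratio is None


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 80)),
        min_size=1,
        max_size=12,
    )
)
def test_normalize_conserves_coverage_property(pairs):
    s = IntervalSet([GenomicInterval("c", a, a + l) for a, l in pairs])
    merged = normalize(s)
    assert merged.total_length() == s.coverage()
    assert normalize(merged) == merged
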