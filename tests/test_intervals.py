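"""Interval types, BED/narrowPeak I/O, and gap-tolerant algebra vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhancerstate.intervals import (
    ChromosomeDialectError,
    GenomicInterval,
    IntervalSet,
    RegionParseError,
    check_chrom_dialects,
    merge_intervals,
    overlaps_with_gap,
    read_regions,
    subset_by_overlap,
    write_regions,
)

from conftest import random_intervals
from oracles import coverage_merge_oracle, gap_oracle, subset_oracle


def as_tuples(iset):
    return [(iv.chrom, iv.start, iv.end) for iv in iset]


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 200, summit_offset=100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 200, strand="x")

    def test_summit_defaults_to_midpoint(self):
        assert GenomicInterval("chr1", 1000, 2000).summit == 1500
        assert GenomicInterval("chr1", 1000, 2000, summit_offset=300).summit == 1300

    def test_set_sorted_and_genome_checked(self):
        s = IntervalSet(
            [GenomicInterval("chr2", 5, 9), GenomicInterval("chr1", 10, 20),
             GenomicInterval("chr1", 3, 8)]
        )
        assert as_tuples(s) == [("chr1", 3, 8), ("chr1", 10, 20), ("chr2", 5, 9)]
        with pytest.raises(ValueError):
            IntervalSet([GenomicInterval("chr1", 10, 200)], genome={"chr1": 100})


class TestIO:
    def test_bed3_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        s = read_regions(p, dialect="bed3")
        assert as_tuples(s) == [("chr1", 100, 200)]

    def test_narrowpeak_summit_and_missing_summit(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text(
            "chr1\t100\t600\tpeak1\t0\t.\t5.5\t-1\t-1\t300\n"
            "chr1\t700\t900\tpeak2\t0\t.\t2.0\t-1\t-1\t-1\n"
        )
        s = read_regions(p)
        assert s[0].summit_offset == 300
        assert s[1].summit_offset is None

    def test_malformed_lines_name_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t500\t400\n")
        with pytest.raises(RegionParseError, match=":2:"):
            read_regions(p, dialect="bed3")
        p.write_text("chr1\t100\t200\nchr1\tx\t400\n")
        with pytest.raises(RegionParseError, match=":2:"):
            read_regions(p, dialect="bed3")
        with pytest.raises(ValueError, match="dialect"):
            read_regions(p, dialect="bed99")

    def test_comment_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("# hello\ntrack name=x\nchr1\t1\t2\n")
        assert len(read_regions(p, dialect="bed3")) == 1

    def test_empty_set_roundtrip(self, tmp_path):
        p = tmp_path / "e.bed"
        write_regions(IntervalSet(), p)
        assert read_regions(p) == IntervalSet()

    @pytest.mark.parametrize("dialect", ["bed6", "narrowPeak", "tsv"])
    def test_roundtrip_random_sets(self, rng, tmp_path, dialect):
        """write o read = identity on 100 random sets for every dialect."""
        for i in range(100):
            ivs = []
            for j in range(int(rng.integers(0, 12))):
                start = int(rng.integers(0, 10_000))
                length = int(rng.integers(1, 500))
                summit = int(rng.integers(0, length)) if rng.random() < 0.5 else None
                if dialect == "bed6":
                    summit = None
                ivs.append(
                    GenomicInterval(
                        f"chr{rng.integers(1, 4)}", start, start + length,
                        name=f"iv{j}",
                        score=float(np.round(rng.random() * 100, 3)),
                        strand=".",
                        summit_offset=summit,
                    )
                )
            original = IntervalSet(ivs)
            p = tmp_path / f"rt_{dialect}_{i}"
            write_regions(original, p, dialect=dialect)
            back = read_regions(p, dialect="auto" if dialect != "tsv" else "tsv")
            assert back == original

    def test_chrom_alias_normalization(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("1\t100\t200\n")
        s = read_regions(p, dialect="bed3", chrom_aliases={"1": "chr1"})
        assert s[0].chrom == "chr1"

    def test_dialect_mismatch_detected(self):
        a = IntervalSet([GenomicInterval("chr1", 1, 2)])
        b = IntervalSet([GenomicInterval("1", 1, 2)])
        with pytest.raises(ChromosomeDialectError, match="disagree"):
            check_chrom_dialects({"a.bed": a, "b.bed": b})
        check_chrom_dialects({"a.bed": a, "b.bed": a})  # consistent: no error


class TestMerge:
    def test_empty_and_overlapping_pair(self):
        assert len(merge_intervals(IntervalSet(), 0)) == 0
        s = IntervalSet([GenomicInterval("chr1", 100, 200),
                         GenomicInterval("chr1", 150, 250)])
        assert as_tuples(merge_intervals(s, 0)) == [("chr1", 100, 250)]

    def test_touching_intervals_merge_at_gap_zero(self):
        s = IntervalSet([GenomicInterval("chr1", 100, 200),
                         GenomicInterval("chr1", 200, 300)])
        assert as_tuples(merge_intervals(s, 0)) == [("chr1", 100, 300)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals(IntervalSet(), -1)

    @pytest.mark.parametrize("max_gap", [0, 37, 1000])
    def test_matches_coverage_oracle(self, rng, max_gap):
        """200 random intervals agree with the per-base boolean-coverage oracle."""
        for _ in range(40):
            s = random_intervals(rng, 200)
            assert as_tuples(merge_intervals(s, max_gap)) == coverage_merge_oracle(
                s, max_gap
            )

    def test_idempotent_and_monotone_in_gap(self, rng):
        for _ in range(20):
            s = random_intervals(rng, 100)
            g = int(rng.integers(0, 200))
            once = merge_intervals(s, g)
            assert merge_intervals(once, g) == once
            bigger = merge_intervals(s, g + int(rng.integers(1, 500)))
            for iv in once:
                assert any(
                    b.chrom == iv.chrom and b.start <= iv.start and iv.end <= b.end
                    for b in bigger
                )


class TestOverlapsWithGap:
    def test_threshold_arithmetic(self):
        a = GenomicInterval("chr1", 100, 200)
        assert overlaps_with_gap(a, GenomicInterval("chr1", 1150, 1300), 1000)
        assert not overlaps_with_gap(a, GenomicInterval("chr1", 1201, 1300), 1000)
        assert overlaps_with_gap(a, a, 0)
        assert overlaps_with_gap(a, GenomicInterval("chr1", 200, 300), 0)  # touching
        assert not overlaps_with_gap(a, GenomicInterval("chr2", 100, 200), 10**9)

    @given(
        s1=st.integers(0, 3000), l1=st.integers(1, 400),
        s2=st.integers(0, 3000), l2=st.integers(1, 400),
        gap=st.integers(0, 1500),
    )
    @settings(derandomize=True, max_examples=200)
    def test_symmetric_and_matches_gap_oracle(self, s1, l1, s2, l2, gap):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        assert overlaps_with_gap(a, b, gap) == overlaps_with_gap(b, a, gap)
        assert overlaps_with_gap(a, b, gap) == (gap_oracle(a, b) <= gap)


class TestSubsetByOverlap:
    def test_self_and_empty_subject(self, rng):
        q = random_intervals(rng, 30)
        assert subset_by_overlap(q, q, 0) == q
        assert subset_by_overlap(q, IntervalSet(), 0, invert=True) == q
        assert len(subset_by_overlap(q, IntervalSet(), 0)) == 0

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(100):
            q = random_intervals(rng, 100)
            s = random_intervals(rng, 100)
            gap = int(rng.choice([0, 50, 1000]))
            for invert in (False, True):
                got = subset_by_overlap(q, s, gap, invert)
                assert as_tuples(got) == as_tuples(
                    IntervalSet(subset_oracle(q, s, gap, invert))
                )

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        q = random_intervals(rng, 150)
        s = random_intervals(rng, 80)
        hit = subset_by_overlap(q, s, 200, invert=False)
        miss = subset_by_overlap(q, s, 200, invert=True)
        assert len(hit) + len(miss) == len(q)
        assert sorted(as_tuples(hit) + as_tuples(miss)) == sorted(as_tuples(q))
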