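from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contigmix.io_model import Alignment, AlignmentSet
from contigmix.preprocess import (
    clean,
    dedupe_reciprocal,
    detect_spurious,
    filter_by_length,
    filter_containment,
    remove_self_alignments,
)

from conftest import aset_from, make_contigs

CONTIGS = make_contigs(
    {"A": 1000, "B": 1000, "C": 1000, "D": 1000, "W": 800, "Q": 400,
     **{f"P{k}": 500 for k in range(1, 7)}}
)


class TestRule1Self:
    def test_removes_self(self):
        aset = aset_from([("A", "A", 0, 200, 0, 200), ("A", "B", 0, 200, 0, 200)], CONTIGS)
        out = remove_self_alignments(aset)
        assert [a.pair for a in out] == [("A", "B")]

    def test_identity_when_clean(self):
        aset = aset_from([("A", "B", 0, 200, 0, 200)], CONTIGS)
        assert remove_self_alignments(aset).alignments == aset.alignments

    def test_empty(self):
        assert len(remove_self_alignments(aset_from([], CONTIGS))) == 0


class TestRule2Reciprocal:
    def test_same_region_deduped(self):
        aset = aset_from(
            [("A", "B", 0, 20, 0, 20), ("B", "A", 0, 20, 0, 20)], CONTIGS
        )
        out = dedupe_reciprocal(aset)
        assert len(out) == 1
        assert out.alignments[0].pair == ("A", "B")  # lexicographic survivor

    def test_disjoint_regions_both_kept(self):
        # projections on A: [0,20) vs [50,70) -- disjoint, so not duplicates
        aset = aset_from(
            [("A", "B", 0, 20, 0, 20), ("B", "A", 100, 120, 50, 70)], CONTIGS
        )
        assert len(dedupe_reciprocal(aset)) == 2

    def test_single_alignment_unchanged(self):
        aset = aset_from([("A", "B", 0, 20, 0, 20)], CONTIGS)
        assert dedupe_reciprocal(aset).alignments == aset.alignments


class TestRule3Length:
    def test_above_threshold_kept(self):
        aset = aset_from([("A", "B", 0, 120, 0, 120)], CONTIGS)
        assert len(filter_by_length(aset, 100)) == 1

    def test_equal_threshold_removed(self):
        # strict inequality: l must be greater than t_a
        aset = aset_from([("A", "B", 0, 100, 0, 100)], CONTIGS)
        assert len(filter_by_length(aset, 100)) == 0

    def test_zero_threshold_keeps_all(self):
        aset = aset_from([("A", "B", 0, 1, 0, 1)], CONTIGS)
        assert len(filter_by_length(aset, 0)) == 1

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_by_length(aset_from([], CONTIGS), -1)


class TestRule4Containment:
    def test_over_99_percent_removed(self):
        aset = aset_from([("A", "B", 0, 995, 0, 995)], CONTIGS)  # 99.5%
        assert len(filter_containment(aset)) == 0

    def test_exactly_99_percent_kept(self):
        contigs = make_contigs({"A": 1000, "B": 2000})
        aset = aset_from([("A", "B", 10, 1000, 0, 990)], contigs)  # 99.0%
        assert len(filter_containment(aset)) == 1

    def test_small_alignment_kept(self):
        aset = aset_from([("A", "B", 0, 10, 0, 10)], CONTIGS)
        assert len(filter_containment(aset)) == 1


class TestRule5Spurious:
    def test_outlier_flagged(self):
        contigs = make_contigs(
            {x: 1000 for x in "ABCDE"} | {f"F{k}": 1000 for k in range(40)}
        )
        rows = []
        rows += [("A", "B", 0, 300, 0, 300), ("A", "C", 0, 300, 0, 300)]
        rows += [("B", "D", 0, 300, 0, 300)]
        rows += [("C", "D", 0, 300, 0, 300)]
        for k in range(36):
            rows.append(("E", f"F{k}", 0, 300, 0, 300))
        rows += [("E", "F36", 0, 300, 0, 300), ("E", "F37", 0, 300, 0, 300),
                 ("E", "F38", 0, 300, 0, 300), ("E", "F39", 0, 300, 0, 300)]
        aset = aset_from(rows, contigs)
        # counts: E=40, A..D=2, F*=1 -> IQR degenerates to 0, fallback
        # fence 3*median = 3 -> only E is flagged
        assert detect_spurious(aset) == {"E"}

    def test_equal_counts_no_outlier(self):
        aset = aset_from(
            [("A", "B", 0, 300, 0, 300), ("C", "D", 0, 300, 0, 300)], CONTIGS
        )
        assert detect_spurious(aset) == set()

    def test_empty(self):
        assert detect_spurious(aset_from([], CONTIGS)) == set()

    def test_quartile_vector_from_counts(self):
        # the documented example distribution {2,3,2,3,40}: fence Q3+3*IQR=6
        import numpy as np

        values = np.array([2.0, 3.0, 2.0, 3.0, 40.0])
        q1, q3 = np.percentile(values, [25, 75])
        assert (q1, q3) == (2.0, 3.0)
        assert 40 > q3 + 3 * (q3 - q1)
        assert all(v <= q3 + 3 * (q3 - q1) for v in values[:-1])


def twelve_alignment_fixture() -> AlignmentSet:
    """Hand-built set: one self, one reciprocal dup, one short (l == t_a),
    one containment, and a spurious contig W with six alignments."""
    rows = [
        ("A", "A", 0, 200, 0, 200),          # 1 rule 1
        ("A", "B", 800, 1000, 0, 200),       # 2 kept
        ("B", "A", 0, 200, 800, 1000),       # 3 rule 2 (dup of 2)
        ("A", "C", 900, 1000, 0, 100),       # 4 rule 3 (l = t_a = 100)
        ("C", "D", 0, 995, 0, 995),          # 5 rule 4 (99.5%)
        ("C", "D", 10, 1000, 0, 990),        # 6 kept (exactly 99%)
    ] + [("W", f"P{k}", 0, 150, 0, 150) for k in range(1, 7)]  # 7-12 rule 5
    return aset_from(rows, CONTIGS)


class TestClean:
    def test_hand_computed_survivors_and_report(self):
        aset = twelve_alignment_fixture()
        out, report = clean(aset, t_a=100)
        assert report.removed_self == 1
        assert report.removed_reciprocal == 1
        assert report.removed_short == 1
        assert report.removed_contained == 1
        assert report.removed_spurious == 6
        assert report.spurious_contig_ids == {"W"}
        assert report.total_removed == len(aset) - len(out) == 10
        survivors = {a.key() for a in out}
        assert survivors == {
            ("A", "B", 800, 1000, 0, 200, False),
            ("C", "D", 10, 1000, 0, 990, False),
        }

    def test_clean_set_unchanged(self):
        aset = aset_from(
            [("A", "B", 800, 1000, 0, 200), ("C", "D", 700, 1000, 0, 300)], CONTIGS
        )
        out, report = clean(aset, t_a=100)
        assert out.alignments == aset.alignments
        assert report.total_removed == 0

    def test_empty(self):
        out, report = clean(aset_from([], CONTIGS), t_a=100)
        assert len(out) == 0 and report.total_removed == 0

    def test_output_never_references_spurious_contig(self):
        out, report = clean(twelve_alignment_fixture(), t_a=100)
        for a in out:
            assert a.ci not in report.spurious_contig_ids
            assert a.cj not in report.spurious_contig_ids


# --- property tests -------------------------------------------------------

_CIDS = ["A", "B", "C", "D", "W"]


@st.composite
def random_aset(draw) -> AlignmentSet:
    n = draw(st.integers(0, 12))
    rows = []
    for _ in range(n):
        ci = draw(st.sampled_from(_CIDS))
        cj = draw(st.sampled_from(_CIDS))
        li = len(CONTIGS[ci])
        lj = len(CONTIGS[cj])
        l = draw(st.integers(1, 400))
        bi = draw(st.integers(0, li - l)) if li > l else 0
        bj = draw(st.integers(0, lj - l)) if lj > l else 0
        rows.append((ci, cj, bi, bi + min(l, li), bj, bj + min(l, lj)))
    rows = [r for r in rows if r[3] - r[2] == r[5] - r[4]]
    return aset_from(rows, CONTIGS)


@given(random_aset(), st.integers(0, 300))
@settings(max_examples=60, deadline=None)
def test_clean_is_idempotent(aset, t_a):
    once, _ = clean(aset, t_a)
    twice, report2 = clean(once, t_a)
    assert twice.alignments == once.alignments
    assert report2.total_removed == 0


@given(random_aset(), st.integers(0, 200), st.integers(0, 200))
@settings(max_examples=60, deadline=None)
def test_survivors_monotone_in_ta(aset, k1, k2):
    lo, hi = min(k1, k2), max(k1, k2)
    keys_hi = {a.key() for a in filter_by_length(aset, hi)}
    keys_lo = {a.key() for a in filter_by_length(aset, lo)}
    assert keys_hi <= keys_lo
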