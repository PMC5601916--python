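"""Unit tests for peak quantification, overlap algebra, and dependency calls."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from conftest import make_cistrome
from corepressor_map import cistrome as ci


class TestRpm:
    def test_arithmetic(self):
        assert ci.compute_rpm(200, 10_000_000) == pytest.approx(20.0)
        assert ci.compute_rpm(0, 10_000_000) == 0.0

    def test_rptm_is_ten_times_rpm(self):
        assert ci.rptm(200, 10_000_000) == pytest.approx(10 * 20.0)

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ValueError):
            ci.compute_rpm(5, 0)


def _random_cistrome(rng, n=100, factor="A", chroms=("chr1", "chr2"),
                     span=1_000_000, width_range=(100, 600), lib=1_000_000):
    rows = []
    for i in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(*width_range))
        rows.append(
            (
                f"{factor}{i:04d}",
                chroms[int(rng.integers(len(chroms)))],
                start,
                start + width,
                int(rng.integers(0, 40)),
                int(rng.integers(0, 5)),
            )
        )
    return make_cistrome(rows, factor=factor, library_size=lib)


class TestFilter:
    def test_kept_when_above_both_gates(self):
        c = make_cistrome([("p1", "chr1", 0, 100, 25, 5)], library_size=10_000_000)
        # rpm 2.5, input_rpm 0.5: passes min_rpm 2 and 3x input
        out = ci.filter_peaks(c, min_rpm=2.0, input_fold=3.0)
        assert list(out.peaks["peak_id"]) == ["p1"]

    def test_dropped_by_input_gate(self):
        c = make_cistrome([("p1", "chr1", 0, 100, 25, 10)], library_size=10_000_000)
        # rpm 2.5 vs 3 x input_rpm 1.0
        out = ci.filter_peaks(c, min_rpm=2.0, input_fold=3.0)
        assert len(out) == 0

    def test_negative_threshold_rejected(self, rng):
        c = _random_cistrome(rng, 5)
        with pytest.raises(ValueError):
            ci.filter_peaks(c, min_rpm=-1)

    def test_matches_filter_oracle(self, rng):
        c = _random_cistrome(rng, 200)
        out = ci.filter_peaks(c, min_rpm=10.0, input_fold=3.0)
        peaks = c.peaks.to_dict("records")
        expected = oracles.filter_oracle(peaks, 10.0, 3.0, pc=0.1)
        assert set(out.peaks["peak_id"]) == expected


class TestOverlap:
    def test_half_overlap_with_enough_signal_is_cobound(self):
        a = make_cistrome([("a1", "chr1", 0, 100, 3, 0)])
        b = make_cistrome([("b1", "chr1", 50, 150, 3, 0)], factor="B")
        part = ci.overlap_cistromes(a, b, min_frac=0.5, min_other_rpm=1.0)
        assert part.co_a == ["a1"] and part.co_b == ["b1"]

    def test_ten_percent_overlap_stays_single(self):
        a = make_cistrome([("a1", "chr1", 0, 100, 3, 0)])
        b = make_cistrome([("b1", "chr1", 90, 200, 3, 0)], factor="B")
        part = ci.overlap_cistromes(a, b)
        assert part.a_only == ["a1"] and part.b_only == ["b1"]
        assert part.co_a == [] and len(part.pairs) == 0

    def test_low_partner_signal_blocks_cobinding(self):
        a = make_cistrome([("a1", "chr1", 0, 100, 3, 0)], library_size=1_000_000)
        # partner rpm 0.5 < 1; a's own rpm 3 qualifies the pair from b's side
        # only if overlap covers half of b -- here b is 4x longer
        b = make_cistrome([("b1", "chr1", 50, 450, 1, 0)], factor="B",
                          library_size=2_000_000)
        part = ci.overlap_cistromes(a, b)
        assert part.co_a == []

    def test_chromosome_mismatch_raises(self):
        a = make_cistrome([("a1", "chrX", 0, 100, 3, 0)])
        b = make_cistrome([("b1", "chr1", 0, 100, 3, 0)], factor="B")
        with pytest.raises(ValueError, match="chrX|chr1"):
            ci.overlap_cistromes(a, b)

    def test_partition_covers_and_is_disjoint(self, rng):
        a = _random_cistrome(rng, 150, "A")
        b = _random_cistrome(rng, 150, "B")
        part = ci.overlap_cistromes(a, b)
        assert set(part.co_a) | set(part.a_only) == set(a.peaks["peak_id"])
        assert not (set(part.co_a) & set(part.a_only))
        assert set(part.co_b) | set(part.b_only) == set(b.peaks["peak_id"])

    def test_symmetry_under_argument_swap(self, rng):
        a = _random_cistrome(rng, 120, "A")
        b = _random_cistrome(rng, 120, "B")
        ab = ci.overlap_cistromes(a, b)
        ba = ci.overlap_cistromes(b, a)
        assert ab.co_a == ba.co_b and ab.a_only == ba.b_only
        assert ab.co_b == ba.co_a and ab.b_only == ba.a_only

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_all_pairs_oracle(self, rng, trial):
        a = _random_cistrome(rng, 200, "A")
        b = _random_cistrome(rng, 200, "B")
        part = ci.overlap_cistromes(a, b)
        co_a, co_b = oracles.overlap_partition_oracle(
            a.peaks.to_dict("records"), b.peaks.to_dict("records")
        )
        assert set(part.co_a) == co_a and set(part.co_b) == co_b

    def test_scale_invariance(self, rng):
        rows = [
            (f"a{i}", "chr1", i * 1000, i * 1000 + 300,
             int(rng.integers(1, 50)), int(rng.integers(0, 3)))
            for i in range(50)
        ]
        rows_b = [
            (f"b{i}", "chr1", i * 1000 + 100, i * 1000 + 400,
             int(rng.integers(1, 50)), int(rng.integers(0, 3)))
            for i in range(50)
        ]
        a1 = make_cistrome(rows, library_size=1_000_000)
        b1 = make_cistrome(rows_b, factor="B", library_size=1_000_000)
        scaled = lambda rows, k: [
            (pid, c, s, e, r * k, ir * k) for pid, c, s, e, r, ir in rows
        ]
        a2 = make_cistrome(scaled(rows, 7), library_size=7_000_000)
        b2 = make_cistrome(scaled(rows_b, 7), factor="B", library_size=7_000_000)
        p1 = ci.overlap_cistromes(a1, b1)
        p2 = ci.overlap_cistromes(a2, b2)
        assert p1.co_a == p2.co_a and p1.b_only == p2.b_only
        dep1 = ci.classify_dependency(a1, make_cistrome(rows, condition="ko"))
        dep2 = ci.classify_dependency(
            a2, make_cistrome(scaled(rows, 7), condition="ko", library_size=7_000_000)
        )
        assert dep1["status"].tolist() == dep2["status"].tolist()


class TestVenn:
    def test_disjoint_and_identical(self):
        rows = [(f"p{i}", "chr1", i * 1000, i * 1000 + 200, 50, 0) for i in range(5)]
        far = [(f"q{i}", "chr1", 500_000 + i * 1000, 500_000 + i * 1000 + 200, 50, 0)
               for i in range(4)]
        a = make_cistrome(rows)
        assert ci.venn_counts(
            ci.overlap_cistromes(a, make_cistrome(far, factor="B"))
        ) == {"co_bound": 0, "a_only": 5, "b_only": 4}
        rows_b = [(pid.replace("p", "b"), c, s, e, r, i)
                  for pid, c, s, e, r, i in rows]
        assert ci.venn_counts(
            ci.overlap_cistromes(a, make_cistrome(rows_b, factor="B"))
        ) == {"co_bound": 5, "a_only": 0, "b_only": 0}


class TestTriple:
    def _partition(self):
        a = make_cistrome([("a1", "chr1", 0, 100, 30, 0),
                           ("a2", "chr1", 10_000, 10_100, 30, 0)])
        b = make_cistrome([("b1", "chr1", 0, 100, 30, 0)], factor="B")
        return a, b, ci.overlap_cistromes(a, b)

    def test_saturating_c_gives_fraction_one(self):
        a, b, part = self._partition()
        c = make_cistrome([("c1", "chr1", 0, 100, 30, 0),
                           ("c2", "chr1", 10_000, 10_100, 30, 0)], factor="C")
        out = ci.triple_intersection(part, a, b, c)
        assert out["fractions"]["co_bound"] == 1.0
        assert out["triple_bound"] == ["a1"]

    def test_disjoint_c_gives_fraction_zero(self):
        a, b, part = self._partition()
        c = make_cistrome([("c1", "chr1", 500_000, 500_100, 30, 0)], factor="C")
        out = ci.triple_intersection(part, a, b, c)
        assert out["fractions"]["co_bound"] == 0.0

    def test_empty_cobound_set_rejected(self):
        a = make_cistrome([("a1", "chr1", 0, 100, 30, 0)])
        b = make_cistrome([("b1", "chr1", 50_000, 50_100, 30, 0)], factor="B")
        part = ci.overlap_cistromes(a, b)
        c = make_cistrome([("c1", "chr1", 0, 100, 30, 0)], factor="C")
        with pytest.raises(ValueError, match="empty co-bound"):
            ci.triple_intersection(part, a, b, c)


class TestDependency:
    def test_pseudocounted_fold_and_status(self):
        ctl = make_cistrome([("p1", "chr1", 0, 100, 40, 0)], library_size=10_000_000)
        ko = make_cistrome([("p1", "chr1", 0, 100, 15, 0)], condition="ko",
                           library_size=10_000_000)
        out = ci.classify_dependency(ctl, ko, fold=2.0, pseudocount=0.1)
        # rpm 4.0 vs 1.5 with 0.1 pseudocount
        assert out["fold_decrease"].iloc[0] == pytest.approx(4.1 / 1.6)
        assert out["status"].iloc[0] == "lost"

    def test_equal_conditions_unchanged(self):
        ctl = make_cistrome([("p1", "chr1", 0, 100, 40, 0)])
        ko = make_cistrome([("p1", "chr1", 0, 100, 40, 0)], condition="ko")
        out = ci.classify_dependency(ctl, ko)
        assert out["fold_decrease"].iloc[0] == pytest.approx(1.0)
        assert out["status"].iloc[0] == "unchanged"

    def test_id_mismatch_rejected(self):
        ctl = make_cistrome([("p1", "chr1", 0, 100, 40, 0)])
        ko = make_cistrome([("p2", "chr1", 0, 100, 40, 0)], condition="ko")
        with pytest.raises(ValueError, match="only one condition"):
            ci.classify_dependency(ctl, ko)

    def test_knockout_persistence_filter(self):
        ctl = make_cistrome([("p1", "chr1", 0, 100, 40, 0),
                             ("p2", "chr1", 1000, 1100, 40, 0)])
        ko = make_cistrome([("p1", "chr1", 0, 100, 2, 0),
                            ("p2", "chr1", 1000, 1100, 35, 0)], condition="ko")
        out = ci.filter_on_knockout(ctl, ko, persist_frac=0.5)
        assert list(out.peaks["peak_id"]) == ["p1"]


class TestCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = _random_cistrome(rng, 50)
        b = make_cistrome(
            [(pid + "_b", c, s, e, r, i)
             for pid, c, s, e, r, i in a.peaks[
                 ["peak_id", "chrom", "start", "end", "reads", "input_reads"]
             ].itertuples(index=False)],
            factor="B",
        )
        assert ci.correlate_cistromes(a, b) == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self, rng):
        a = _random_cistrome(rng, 60, "A")
        b = _random_cistrome(rng, 60, "B")
        union = ci._union_intervals(a.peaks, b.peaks)
        x = ci._signal_over(union, a)
        y = ci._signal_over(union, b)
        assert ci.correlate_cistromes(a, b) == pytest.approx(
            oracles.pearson_r_oracle(x, y), abs=1e-12
        )

    def test_independent_noise_is_uncorrelated(self, rng):
        # disjoint random peaks: rpm vectors over the union have no shared signal
        n = 3000
        rows_a, rows_b = [], []
        for i in range(n):
            base = i * 2000
            rows_a.append((f"a{i}", "chr1", base, base + 400,
                           int(rng.poisson(30)) + 1, 0))
            rows_b.append((f"b{i}", "chr1", base + 100, base + 500,
                           int(rng.poisson(30)) + 1, 0))
        r = ci.correlate_cistromes(make_cistrome(rows_a),
                                   make_cistrome(rows_b, factor="B"))
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        rows = [(f"p{i}", "chr1", i * 1000, i * 1000 + 100, 10, 0) for i in range(5)]
        a = make_cistrome(rows)
        b = make_cistrome([(p + "b", c, s, e, r, i) for p, c, s, e, r, i in rows],
                          factor="B")
        with pytest.raises(ValueError, match="zero-variance"):
            ci.correlate_cistromes(a, b)

    def test_too_few_union_peaks_rejected(self):
        a = make_cistrome([("a1", "chr1", 0, 100, 10, 0)])
        b = make_cistrome([("b1", "chr1", 50, 150, 20, 0)], factor="B")
        with pytest.raises(ValueError, match=">= 3"):
            ci.correlate_cistromes(a, b)
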