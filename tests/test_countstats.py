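"""Pooling, signed ratio, calibration, exact test, BH, selection, partition."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speccount import (
    DifferentialRecord,
    GroupPool,
    PseudocountConfig,
    SelectionPolicy,
    bh_adjust,
    calibrate_total_ratio,
    categorize,
    compute_rsc,
    differential_analysis,
    fisher_test,
    pool_counts,
    presence_breakdown,
    select_differential,
    signed_ratio,
)

from conftest import bh_oracle, fisher_two_sided_oracle, make_matrix


class TestPoolCounts:
    def test_ref_only_protein(self, two_group_annotation):
        matrix = make_matrix({"P": [5, 15, 0, 0]}, two_group_annotation)
        pool = pool_counts(matrix, "REF", "CMP")["P"]
        assert pool.n_ref == 20
        assert pool.n_cmp == 0
        assert pool.present_cmp == 0
        assert pool.present_ref == 2

    def test_single_protein_totals_equal_counts(self, two_group_annotation):
        matrix = make_matrix({"P": [3, 4, 5, 6]}, two_group_annotation)
        pool = pool_counts(matrix)["P"]
        assert pool.N_ref == pool.n_ref == 7
        assert pool.N_cmp == pool.n_cmp == 11

    def test_group_totals_match_summation_oracle(self, two_group_annotation, rng):
        rows = {f"P{i}": list(rng.integers(0, 30, 4)) for i in range(100)}
        matrix = make_matrix(rows, two_group_annotation)
        pools = pool_counts(matrix, "REF", "CMP")
        expected_N_ref = sum(counts[0] + counts[1] for counts in rows.values())
        expected_N_cmp = sum(counts[2] + counts[3] for counts in rows.values())
        for pool in pools.values():
            assert pool.N_ref == expected_N_ref
            assert pool.N_cmp == expected_N_cmp

    def test_unknown_group_errors(self, two_group_annotation):
        matrix = make_matrix({"P": [1, 1, 1, 1]}, two_group_annotation)
        with pytest.raises(ValueError):
            pool_counts(matrix, "REF", "NOPE")


class TestSignedRatio:
    def test_calibrated_unique_example(self):
        # comparison-unique protein, pooled counts 0 vs 21, scale 1.12
        _, rsc = signed_ratio(0, 21, total_ratio=1.12, f=1.25)
        assert rsc == pytest.approx(19.9, abs=0.1)

    def test_symmetry_at_equality(self):
        pool = GroupPool(n_ref=10, n_cmp=10, N_ref=100, N_cmp=100)
        raw, rsc = compute_rsc(pool)
        assert raw == 1.0
        assert rsc == 1.0

    def test_reference_unique_hand_arithmetic(self):
        pool = GroupPool(n_ref=21, n_cmp=0, N_ref=1000, N_cmp=1000)
        raw, rsc = compute_rsc(pool, PseudocountConfig(f=1.25))
        assert raw == pytest.approx(1.25 / 22.25)
        assert rsc == pytest.approx(-22.25 / 1.25)
        assert rsc == pytest.approx(-17.8, abs=0.1)

    def test_non_positive_totals_error(self):
        with pytest.raises(ValueError):
            signed_ratio(1, 1, total_ratio=0.0)

    @given(
        n_ref=st.integers(min_value=0, max_value=200),
        n_cmp=st.integers(min_value=0, max_value=200),
        ratio=st.floats(min_value=0.1, max_value=10.0),
        f=st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_sign_convention_and_magnitude(self, n_ref, n_cmp, ratio, f):
        raw, rsc = signed_ratio(n_ref, n_cmp, ratio, f)
        assert raw > 0
        assert abs(rsc) >= 1.0
        if raw >= 1:
            assert rsc == raw
        else:
            assert rsc == pytest.approx(-1.0 / raw)

    @given(
        n_ref=st.integers(min_value=0, max_value=100),
        n_cmp=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_group_swap_antisymmetry(self, n_ref, n_cmp):
        pool = GroupPool(n_ref=n_ref, n_cmp=n_cmp, N_ref=500, N_cmp=400)
        raw, rsc = compute_rsc(pool)
        raw_swapped, rsc_swapped = compute_rsc(pool.swapped())
        assert raw_swapped == pytest.approx(1.0 / raw)
        if abs(rsc) > 1:
            assert rsc_swapped == pytest.approx(-rsc)

    def test_monotonicity_in_counts(self):
        base = signed_ratio(10, 10, 1.0)[1]
        assert signed_ratio(10, 11, 1.0)[1] > base
        up = signed_ratio(10, 30, 1.0)[0]
        assert signed_ratio(11, 30, 1.0)[0] < up


class TestCalibration:
    def test_single_row(self):
        r = calibrate_total_ratio([(1, 23, 12.1)], PseudocountConfig(1.25))
        assert r == pytest.approx(12.1 * 2.25 / 24.25)
        assert r == pytest.approx(1.1227, abs=1e-4)

    def test_noiseless_recovery_exact(self, rng):
        r_star = 1.2345
        f = 1.25
        rows = []
        for _ in range(12):
            n_ref = int(rng.integers(0, 40))
            n_cmp = int(rng.integers(0, 40))
            raw, rsc = signed_ratio(n_ref, n_cmp, r_star, f)
            rows.append((n_ref, n_cmp, rsc))
        assert calibrate_total_ratio(rows) == pytest.approx(r_star, rel=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            calibrate_total_ratio([])


class TestFisher:
    def test_identical_proportions(self):
        pool = GroupPool(n_ref=1, n_cmp=1, N_ref=10, N_cmp=10)
        assert fisher_test(pool) == 1.0

    def test_enumerated_small_table(self):
        pool = GroupPool(n_ref=2, n_cmp=0, N_ref=2, N_cmp=2)
        assert fisher_test(pool) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_degenerate_margin(self):
        pool = GroupPool(n_ref=0, n_cmp=0, N_ref=10, N_cmp=10)
        assert fisher_test(pool) == 1.0

    def test_matches_enumeration_oracle_small_margins(self, rng):
        for _ in range(400):
            N_ref = int(rng.integers(1, 13))
            N_cmp = int(rng.integers(1, 13))
            n_ref = int(rng.integers(0, N_ref + 1))
            n_cmp = int(rng.integers(0, N_cmp + 1))
            pool = GroupPool(n_ref=n_ref, n_cmp=n_cmp, N_ref=N_ref, N_cmp=N_cmp)
            expected = fisher_two_sided_oracle(n_ref, N_ref, n_cmp, N_cmp)
            assert fisher_test(pool) == pytest.approx(expected, abs=1e-12), (
                n_ref, N_ref, n_cmp, N_cmp,
            )

    def test_large_totals_realistic_scale(self):
        pool = GroupPool(n_ref=5, n_cmp=40, N_ref=25_000, N_cmp=22_000)
        p = fisher_test(pool)
        assert 0 < p < 1e-5


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_naive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, n)
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=50
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_order(self, p_values):
        q = bh_adjust(p_values)
        assert np.all(q >= np.asarray(p_values) - 1e-15)
        assert np.all(q <= 1.0)
        # adjusted values preserve the p-value ordering
        order = np.argsort(p_values, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


def _diff_record(accession, n_ref, n_cmp, p, rsc, selected=False):
    return DifferentialRecord(
        accession=accession,
        gene_symbol=f"g{accession}",
        description="",
        pool=GroupPool(n_ref=n_ref, n_cmp=n_cmp, N_ref=10_000, N_cmp=10_000),
        raw_ratio=abs(rsc) if rsc > 0 else 1.0 / abs(rsc),
        rsc=rsc,
        p_value=p,
        q_value=p,
        selected=selected,
    )


class TestSelection:
    def test_both_criteria_met(self):
        record = _diff_record("A", 1, 10, p=0.04, rsc=2.5)
        assert select_differential([record]) == [record]
        assert record.selected

    def test_fold_threshold_strict(self):
        record = _diff_record("A", 5, 10, p=0.04, rsc=1.9)
        assert select_differential([record]) == []
        boundary = _diff_record("B", 5, 10, p=0.04, rsc=2.0)
        assert select_differential([boundary]) == []

    def test_recount_oracle(self, rng):
        records = [
            _diff_record(
                f"P{i}",
                int(rng.integers(0, 20)),
                int(rng.integers(1, 20)),
                p=float(rng.uniform(1e-4, 1.0)),
                rsc=float(rng.choice([-1, 1]) * rng.uniform(1.0, 6.0)),
            )
            for i in range(1000)
        ]
        selected = select_differential(records)
        recount = sum(
            1 for r in records if r.p_value < 0.05 and abs(r.rsc) > 2.0
        )
        assert len(selected) == recount

    def test_use_adjusted(self):
        record = _diff_record("A", 0, 30, p=0.01, rsc=5.0)
        record.q_value = 0.2
        assert select_differential(
            [record], SelectionPolicy(use_adjusted=True)
        ) == []
        assert select_differential([record], SelectionPolicy()) == [record]


class TestCategorize:
    def test_all_common(self):
        records = [
            _diff_record("A", 3, 30, 0.01, 4.0, selected=True),
            _diff_record("B", 30, 3, 0.01, -4.0, selected=True),
        ]
        summary = categorize(records)
        assert summary.unique_to_ref == summary.unique_to_cmp == 0
        assert summary.common_enriched == 1
        assert summary.common_diminished == 1

    def test_all_ref_unique(self):
        records = [
            _diff_record(f"U{i}", 10 + i, 0, 0.001, -10.0 - i, selected=True)
            for i in range(10)
        ]
        summary = categorize(records)
        assert summary.unique_to_ref == 10
        assert summary.total == 10
        assert all(r.category == "unique_to_ref" for r in records)

    def test_planted_composition(self, rng):
        records = (
            [_diff_record(f"a{i}", 10, 0, 0.01, -5.0, True) for i in range(88)]
            + [_diff_record(f"b{i}", 0, 10, 0.01, 5.0, True) for i in range(67)]
            + [_diff_record(f"c{i}", 2, 10, 0.01, 3.0, True) for i in range(115)]
            + [_diff_record(f"d{i}", 10, 2, 0.01, -3.0, True) for i in range(83)]
        )
        order = rng.permutation(len(records))
        shuffled = [records[i] for i in order]
        summary = categorize(shuffled)
        assert (
            summary.unique_to_ref,
            summary.unique_to_cmp,
            summary.common_enriched,
            summary.common_diminished,
        ) == (88, 67, 115, 83)
        assert summary.total == 353

    def test_zero_zero_rejected(self):
        bad = DifferentialRecord(
            accession="Z",
            gene_symbol="",
            description="",
            pool=GroupPool(n_ref=0, n_cmp=0, N_ref=10, N_cmp=10),
            raw_ratio=1.0,
            rsc=1.0,
            p_value=1.0,
        )
        with pytest.raises(ValueError, match="zero counts"):
            categorize([bad])


class TestPresenceBreakdown:
    def _matrix(self, presence_counts):
        # 4 CMP samples; protein i detected in presence_counts[i] of them
        from speccount import SampleAnnotation

        annotation = [SampleAnnotation(f"R{i}", "REF") for i in range(1, 5)] + [
            SampleAnnotation(f"C{i}", "CMP") for i in range(1, 5)
        ]
        rows = {}
        for i, k in enumerate(presence_counts):
            rows[f"P{i}"] = [1, 1, 1, 1] + [1] * k + [0] * (4 - k)
        return make_matrix(rows, annotation)

    def test_all_present_everywhere(self):
        matrix = self._matrix([4, 4, 4])
        breakdown = presence_breakdown(matrix, [f"P{i}" for i in range(3)], "CMP")
        assert breakdown.fractions[4] == 1.0
        assert breakdown.undetected == ()

    def test_fixture_fractions(self):
        matrix = self._matrix([4, 4, 4, 4, 3, 3, 3, 2, 2, 1])
        breakdown = presence_breakdown(
            matrix, [f"P{i}" for i in range(10)], "CMP"
        )
        assert breakdown.fractions == {4: 0.4, 3: 0.3, 2: 0.2, 1: 0.1}
        assert sum(breakdown.fractions.values()) == pytest.approx(1.0)

    def test_all_zero_protein_reported_separately(self):
        matrix = self._matrix([4, 0])
        breakdown = presence_breakdown(matrix, ["P0", "P1"], "CMP")
        assert breakdown.undetected == ("P1",)
        assert breakdown.fractions[4] == 1.0

    def test_unknown_accession(self):
        matrix = self._matrix([4])
        with pytest.raises(KeyError):
            presence_breakdown(matrix, ["NOPE"], "CMP")


class TestDifferentialAnalysis:
    def test_end_to_end_small(self, small_matrix):
        records, dropped = differential_analysis(small_matrix, "REF", "CMP")
        assert dropped == []
        assert len(records) == 4
        by_acc = {r.accession: r for r in records}
        assert by_acc["P1"].pool.n_cmp == 0
        assert by_acc["P1"].rsc < -1
        assert by_acc["P3"].rsc > 1
        for r in records:
            assert abs(r.rsc) >= 1.0
            assert 0 < r.p_value <= 1.0
            assert r.q_value >= r.p_value - 1e-15

    def test_zero_zero_dropped(self, two_group_annotation):
        matrix = make_matrix(
            {"Z": [0, 0, 0, 0], "A": [1, 1, 2, 2]}, two_group_annotation
        )
        records, dropped = differential_analysis(matrix)
        assert dropped == ["Z"]
        assert [r.accession for r in records] == ["A"]

    def test_partition_conservation(self, two_group_annotation, rng):
        rows = {
            f"P{i}": list(rng.integers(0, 40, 4)) for i in range(200)
        }
        matrix = make_matrix(rows, two_group_annotation)
        records, _ = differential_analysis(matrix)
        selected = [r for r in records if r.selected]
        if selected:
            summary = categorize(selected)
            assert summary.total == len(selected)
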