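"""ROR/PRR/chi-square estimation, signal criteria, ranking, inversion."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pvsignal import datasets
from pvsignal.contingency import ContingencyTable
from pvsignal.stats import (
    InconsistentSummaryError,
    SignalCriteria,
    apply_signal_criteria,
    chi_square,
    compute_prr,
    compute_ror,
    invert_summary,
    rank_signals,
    signal_stats,
)


def table(a, b, c, d):
    return ContingencyTable(drug="drug", event="pt", a=a, b=b, c=c, d=d)


positive_cells = st.integers(min_value=1, max_value=5000)
positive_tables = st.tuples(positive_cells, positive_cells, positive_cells, positive_cells)


class TestPointEstimates:
    def test_ror_balanced_table(self):
        est = compute_ror(table(10, 10, 10, 10))
        assert est.value == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(0.289496, rel=1e-5)
        assert est.ci_high == pytest.approx(3.454276, rel=1e-5)

    def test_ror_reference_table(self):
        est = compute_ror(table(5, 95, 100, 9900))
        assert est.value == pytest.approx(5.210526, rel=1e-6)
        assert est.ci_low == pytest.approx(2.075184, rel=1e-5)
        assert est.ci_high == pytest.approx(13.082980, rel=1e-5)

    def test_prr_reference_table(self):
        assert compute_prr(table(5, 95, 100, 9900)).value == pytest.approx(5.0)

    def test_prr_is_one_under_equal_proportions(self):
        # a/(a+b) = c/(c+d) = 0.1
        assert compute_prr(table(10, 90, 50, 450)).value == pytest.approx(1.0)

    def test_zero_cell_undefined_without_correction(self):
        est = compute_ror(table(0, 10, 10, 10))
        assert not est.defined
        assert math.isnan(est.ci_low)

    def test_haldane_defines_zero_cell_table(self):
        est = compute_ror(table(0, 10, 10, 10), haldane=True)
        assert est.defined
        assert est.value == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))


class TestChiSquare:
    def test_independence_gives_zero(self):
        assert chi_square(table(10, 10, 10, 10)) == pytest.approx(0.0)

    def test_pearson_reference_value(self):
        assert chi_square(table(5, 95, 100, 9900)) == pytest.approx(15.398175, rel=1e-6)

    def test_yates_reference_value(self):
        assert chi_square(table(5, 95, 100, 9900), variant="yates") == pytest.approx(
            11.755568, rel=1e-6
        )

    def test_agrees_with_scipy(self):
        cells = (17, 83, 211, 9689)
        observed = np.array(cells).reshape(2, 2)
        for variant, correction in (("pearson", False), ("yates", True)):
            expected = sps.chi2_contingency(observed, correction=correction)[0]
            assert chi_square(table(*cells), variant=variant) == pytest.approx(expected)

    def test_invariant_under_row_and_column_swap(self):
        t1 = table(7, 21, 13, 402)
        t2 = table(402, 13, 21, 7)  # both rows and both columns swapped
        assert chi_square(t1) == pytest.approx(chi_square(t2))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            chi_square(table(1, 1, 1, 1), variant="wilson")


class TestSignalCriteria:
    @pytest.mark.parametrize(
        "a,ci_low,prr,expected",
        [
            (2, 5.0, 10.0, False),   # count below 3
            (3, 1.001, 2.001, True),
            (3, 1.0, 2.5, False),    # CI bound not strictly above 1
            (3, 1.5, 2.0, False),    # PRR not strictly above 2
            (734, 2.046, 2.090, True),
        ],
    )
    def test_joint_rule(self, a, ci_low, prr, expected):
        flag, _ = apply_signal_criteria((a, ci_low, prr))
        assert flag is expected

    def test_undefined_stats_fail_with_reason(self):
        flag, reason = apply_signal_criteria((10, math.nan, math.nan))
        assert not flag
        assert reason == "undefined"

    def test_custom_thresholds(self):
        strict = SignalCriteria(a_min=100, prr_min=2.0, ror_ci_low_min=1.0)
        flag, reason = apply_signal_criteria((50, 3.0, 5.0), strict)
        assert not flag and "a<100" in reason


class TestRankSignals:
    def test_published_order_death_then_drug_interaction(self):
        rows = datasets.load_triazole_top20()
        stats = []
        for r in rows[rows.drug == "voriconazole"].itertuples():
            inv = invert_summary(r.a, r.prr, r.ror, r.ror_ci_low, r.ror_ci_high)
            t = inv.rounded
            stats.append(
                signal_stats(ContingencyTable(drug="voriconazole", event=r.pt,
                                              a=t.a, b=t.b, c=t.c, d=t.d))
            )
        ranked = rank_signals(stats, n=20)
        assert ranked[0].event == "death" and ranked[0].a == 734
        assert ranked[1].event == "drug interaction" and ranked[1].a == 513

    def test_empty_input(self):
        assert rank_signals([], n=5) == []

    def test_tie_broken_by_ror_then_event(self):
        s1 = signal_stats(table(10, 10, 10, 1000))   # ror 100
        s2 = signal_stats(table(10, 10, 20, 1000))   # ror 50
        ranked = rank_signals([s2, s1])
        assert ranked[0].ror > ranked[1].ror


class TestAlgebraicIdentities:
    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(positive_tables)
    def test_ror_and_prr_on_same_side_of_one(self, cells):
        t = table(*cells)
        ror = compute_ror(t).value
        prr = compute_prr(t).value
        if ror > 1:
            assert ror > prr
        elif ror < 1:
            assert ror < prr
        else:
            assert prr == pytest.approx(1.0)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(positive_tables)
    def test_geometric_mean_of_ci_is_point_estimate(self, cells):
        t = table(*cells)
        for est in (compute_ror(t), compute_prr(t)):
            assert math.sqrt(est.ci_low * est.ci_high) == pytest.approx(
                est.value, rel=1e-9
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.tuples(positive_cells, positive_cells, positive_cells))
    def test_increasing_a_increases_ror_and_prr(self, bcd):
        b, c, d = bcd
        r1, p1 = compute_ror(table(3, b, c, d)).value, compute_prr(table(3, b, c, d)).value
        r2, p2 = compute_ror(table(4, b, c, d)).value, compute_prr(table(4, b, c, d)).value
        assert r2 > r1
        assert p2 > p1


class TestInversion:
    def test_round_trip_recovers_reference_table(self):
        t = table(5, 95, 100, 9900)
        ror = compute_ror(t)
        prr = compute_prr(t)
        inv = invert_summary(5, prr.value, ror.value, ror.ci_low, ror.ci_high)
        for got, want in zip((inv.table.b, inv.table.c, inv.table.d), (95, 100, 9900)):
            assert got == pytest.approx(want, rel=1e-6)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(positive_tables)
    def test_round_trip_on_random_tables(self, cells):
        a, b, c, d = cells
        t = table(a, b, c, d)
        ror = compute_ror(t)
        prr = compute_prr(t)
        if abs(ror.value - prr.value) < 1e-9:  # ROR ~ 1: inversion degenerate
            return
        inv = invert_summary(a, prr.value, ror.value, ror.ci_low, ror.ci_high)
        assert inv.table.b == pytest.approx(b, rel=1e-6)
        assert inv.table.c == pytest.approx(c, rel=1e-6)
        assert inv.table.d == pytest.approx(d, rel=1e-6)

    def test_published_strongest_signal_row_inverts(self):
        # actinic keratosis: a=78, PRR 105.868, ROR 106.965, CI 84.915-134.740
        inv = invert_summary(78, 105.868, 106.965, 84.915, 134.740)
        assert max(inv.residuals.values()) < 0.002
        est = compute_ror(inv.rounded)
        assert est.value == pytest.approx(106.965, rel=0.002)
        assert est.ci_low == pytest.approx(84.915, rel=0.002)
        assert est.ci_high == pytest.approx(134.740, rel=0.002)

    def test_transcription_error_row_rejected(self):
        # PRR 17.083 > ROR 11.383 > 1: impossible for any positive table
        with pytest.raises(InconsistentSummaryError, match="ordering"):
            invert_summary(11, 17.083, 11.383, 7.322, 17.696)

    def test_geometric_mean_violation_rejected(self):
        with pytest.raises(InconsistentSummaryError, match="geometric mean"):
            invert_summary(50, 2.0, 2.5, 1.8, 2.9)

    def test_ci_narrower_than_count_allows_rejected(self):
        # 1/a alone exceeds the squared log-CI half-width
        with pytest.raises(InconsistentSummaryError, match="too narrow"):
            invert_summary(48, 6.08, 6.329, 5.063, 7.912)
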