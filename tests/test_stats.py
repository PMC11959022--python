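"""Disproportionality statistics: worked examples, independent oracles
and structural properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faersignal.stats import (
    ContingencyTable,
    CriteriaThresholds,
    SignalStats,
    build_table,
    ebgm_stat,
    evaluate_criteria,
    ic_stat,
    prr_stat,
    rank_signals,
    reconstruct_table,
    ror_stat,
    signal_stats_for_table,
)

cells = st.integers(min_value=1, max_value=10**6)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)

REFERENCE = ContingencyTable(10, 90, 100, 9800)


class TestContingencyTable:
    def test_arithmetic_from_counts(self):
        class Counts:
            n_target_total = 100
            n_all = 10000

            def term_counts(self, term, level):
                return 10, 110

        t = build_table(Counts(), "X")
        assert t.as_tuple() == (10, 90, 100, 9800)

    def test_degenerate_single_report(self):
        class Counts:
            n_target_total = 1
            n_all = 1

            def term_counts(self, term, level):
                return 1, 1

        assert build_table(Counts(), "X").as_tuple() == (1, 0, 0, 0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ContingencyTable(1, -1, 2, 3)

    def test_inconsistent_counts_rejected(self):
        class Counts:
            n_target_total = 5
            n_all = 10

            def term_counts(self, term, level):
                return 3, 9  # c=6, d=-4

        with pytest.raises(ValueError, match="inconsistent"):
            build_table(Counts(), "X")


class TestRor:
    def test_reference_table(self):
        est = ror_stat(REFERENCE)
        assert est.value == pytest.approx(980 / 90, rel=1e-12)
        assert est.lo == pytest.approx(5.5033, rel=1e-4)
        assert est.hi == pytest.approx(21.5447, rel=1e-4)

    def test_symmetric_table_is_null(self):
        est = ror_stat(ContingencyTable(25, 25, 25, 25))
        assert est.value == 1.0
        assert est.lo < 1.0 < est.hi

    def test_zero_cell_undefined(self):
        est = ror_stat(ContingencyTable(1, 0, 5, 100))
        assert not est.defined
        assert est.reason == "zero-cell"

    @settings(max_examples=100, derandomize=True)
    @given(tables)
    def test_transpose_symmetry(self, t):
        """Swapping b and c leaves the odds ratio invariant."""
        swapped = ContingencyTable(t.a, t.c, t.b, t.d)
        assert ror_stat(t).value == pytest.approx(ror_stat(swapped).value, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(tables)
    def test_monotone_in_a(self, t):
        bigger = ContingencyTable(t.a + 1, t.b, t.c, t.d)
        assert ror_stat(bigger).value > ror_stat(t).value


class TestPrr:
    def test_reference_table(self):
        res = prr_stat(REFERENCE)
        assert res.prr.value == pytest.approx(9.9, rel=1e-12)
        assert res.chi2 == pytest.approx(73.55, abs=0.01)

    def test_independence(self):
        res = prr_stat(ContingencyTable(25, 25, 25, 25))
        assert res.prr.value == 1.0
        assert res.chi2 == 0.0

    def test_defined_with_zero_b(self):
        res = prr_stat(ContingencyTable(1, 0, 5, 100))
        assert res.prr.value == pytest.approx(105 / 5, rel=1e-12)
        assert res.chi2_defined

    def test_zero_a_undefined(self):
        res = prr_stat(ContingencyTable(0, 10, 5, 100))
        assert not res.prr.defined
        assert res.prr.reason == "zero-cell"

    @settings(max_examples=100, derandomize=True)
    @given(tables)
    def test_monotone_in_a(self, t):
        bigger = ContingencyTable(t.a + 1, t.b, t.c, t.d)
        assert prr_stat(bigger).prr.value > prr_stat(t).prr.value

    def test_not_transpose_symmetric(self):
        t = ContingencyTable(10, 90, 100, 9800)
        swapped = ContingencyTable(10, 100, 90, 9800)
        assert prr_stat(t).prr.value != pytest.approx(
            prr_stat(swapped).prr.value, rel=1e-6
        )


class TestIcAndEbgm:
    def test_reference_values(self):
        assert ic_stat(REFERENCE).value == pytest.approx(math.log2(10000 / 1100), rel=1e-12)
        est = ebgm_stat(REFERENCE)
        assert est.value == pytest.approx(10 * 10000 / (110 * 100), rel=1e-12)
        assert est.lo == pytest.approx(4.595, abs=2e-3)

    def test_independence_is_zero_bits(self):
        assert ic_stat(ContingencyTable(25, 25, 25, 25)).value == 0.0
        assert ebgm_stat(ContingencyTable(25, 25, 25, 25)).value == 1.0

    @settings(max_examples=150, derandomize=True)
    @given(tables)
    def test_ic_is_log2_ebgm(self, t):
        assert ic_stat(t).value == pytest.approx(
            math.log2(ebgm_stat(t).value), rel=1e-12
        )

    @settings(max_examples=150, derandomize=True)
    @given(tables)
    def test_interval_brackets_estimate(self, t):
        est = ic_stat(t)
        assert est.lo < est.value < est.hi

    def test_zero_a(self):
        assert not ic_stat(ContingencyTable(0, 10, 5, 100)).defined
        est = ebgm_stat(ContingencyTable(0, 10, 5, 100))
        assert est.value == 0.0 and not est.interval_defined

    def test_bate_estimator_defined_at_zero(self):
        est = ic_stat(ContingencyTable(0, 10, 5, 100), estimator="bate")
        assert est.defined and est.lo < est.value < est.hi

    def test_mc_interval_close_to_closed_form(self):
        t = ContingencyTable(50, 450, 500, 49000)
        closed = ic_stat(t)
        mc = ic_stat(t, interval="mc", rng=np.random.default_rng(1))
        assert mc.lo == pytest.approx(closed.lo, abs=0.25)
        assert mc.hi == pytest.approx(closed.hi, abs=0.25)


@pytest.fixture(scope="module")
def random_tables():
    rng = np.random.default_rng(2024)
    return [
        ContingencyTable(*(int(x) for x in rng.integers(1, 10**6, size=4)))
        for _ in range(1000)
    ]


class TestOracleAgreement:
    """Cross-checks against scipy and statsmodels on random tables."""

    def test_chi2_matches_uncorrected_pearson(self, random_tables):
        from scipy.stats import chi2_contingency

        for t in random_tables:
            ref = chi2_contingency(
                [[t.a, t.b], [t.c, t.d]], correction=False
            ).statistic
            assert prr_stat(t).chi2 == pytest.approx(ref, rel=1e-9, abs=1e-9)

    def test_ror_matches_textbook_log_odds_interval(self, random_tables):
        from statsmodels.stats.contingency_tables import Table2x2

        for t in random_tables[:200]:
            ref = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
            est = ror_stat(t)
            assert est.value == pytest.approx(ref.oddsratio, rel=1e-12)
            lo, hi = ref.oddsratio_confint()
            # the interval uses z = 1.96 rather than the exact quantile
            assert est.lo == pytest.approx(lo, rel=1e-4)
            assert est.hi == pytest.approx(hi, rel=1e-4)


class TestCriteria:
    def _stats(self, t, thresholds=CriteriaThresholds()):
        return signal_stats_for_table("X", "PT", t, thresholds)

    def test_small_n_blocks_ror_flag(self):
        s = self._stats(ContingencyTable(2, 8, 10, 10000))
        assert s.ror.lo > 1  # strong association...
        assert not s.flags["ror"]  # ...but n < 3

    def test_ror_lower_bound_strictly_greater(self):
        s = self._stats(ContingencyTable(50, 50, 500, 5000))
        s.ror.lo = 1.0
        assert not evaluate_criteria(s)["ror"]
        s.ror.lo = 1.0 + 1e-12
        assert evaluate_criteria(s)["ror"]

    def test_prr_boundaries_inclusive(self):
        s = self._stats(ContingencyTable(3, 3, 300, 5000))
        s.prr.prr.value = 2.0
        s.prr.chi2 = 4.0
        assert evaluate_criteria(s)["prr"]
        s.prr.chi2 = 3.999
        assert not evaluate_criteria(s)["prr"]

    def test_undefined_statistic_never_flags(self):
        s = self._stats(ContingencyTable(5, 0, 100, 10000))
        assert not s.flags["ror"]
        assert "ror" in s.undefined_reason

    def test_combined_flags(self):
        s = self._stats(ContingencyTable(100, 100, 100, 100000))
        assert s.flags["any"] == any(
            s.flags[k] for k in ("ror", "prr", "ic", "ebgm")
        )
        assert s.flags["all"] == all(
            s.flags[k] for k in ("ror", "prr", "ic", "ebgm")
        )

    @settings(max_examples=100, derandomize=True)
    @given(tables)
    def test_ror_flag_monotone_in_a(self, t):
        s = self._stats(t)
        if s.flags["ror"]:
            bigger = self._stats(ContingencyTable(t.a + 1, t.b, t.c, t.d))
            assert bigger.flags["ror"]


class TestRanking:
    def _mk(self, term, ebgm, n):
        t = ContingencyTable(n, 10, 10, 1000)
        s = signal_stats_for_table(term, "PT", t)
        s.ebgm.value = ebgm
        return s

    def test_descending_by_ebgm(self):
        ranked = rank_signals([self._mk("lo", 3, 5), self._mk("hi", 5, 5)])
        assert [s.term for s in ranked] == ["hi", "lo"]

    def test_tie_broken_by_n_then_name(self):
        ranked = rank_signals(
            [self._mk("b", 5, 7), self._mk("a", 5, 10), self._mk("c", 5, 7)]
        )
        assert [s.term for s in ranked] == ["a", "b", "c"]

    def test_top_n_and_min_n(self):
        pool = [self._mk(f"t{i}", i, i) for i in range(1, 6)]
        assert rank_signals(pool, top_n=0) == []
        assert len(rank_signals(pool, top_n=2)) == 2
        assert all(s.n > 3 for s in rank_signals(pool, min_n=3))

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="ranking key"):
            rank_signals([], order_key="banana")


class TestReconstruction:
    def test_reference_self_consistency(self):
        est_ror = ror_stat(REFERENCE).value
        est_prr = prr_stat(REFERENCE).prr.value
        t = reconstruct_table(10, 10000, est_ror, est_prr)
        assert t.b == pytest.approx(90, rel=1e-9)
        assert t.c == pytest.approx(100, rel=1e-9)
        assert t.d == pytest.approx(9800, rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_inversion_identity_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a = int(rng.integers(5, 500))
        b = int(rng.integers(100, 5000))
        c = int(rng.integers(100, 50000))
        d = int(rng.integers(10**5, 10**7))
        t = ContingencyTable(a, b, c, d)
        ror = ror_stat(t).value
        prr = prr_stat(t).prr.value
        if not ror > prr > 0:
            pytest.skip("degenerate draw outside the feasible ordering")
        rt = reconstruct_table(a, t.n, ror, prr)
        assert ror_stat(rt).value == pytest.approx(ror, rel=1e-10)
        assert prr_stat(rt).prr.value == pytest.approx(prr, rel=1e-10)

    def test_infeasible_rejected_with_residuals(self):
        with pytest.raises(ValueError, match="ROR > PRR"):
            reconstruct_table(10, 10000, 2.0, 5.0)
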