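"""2x2 estimators, exact test, t-test, logistic fit and BH-FDR."""

import math

import hypothesis.strategies as st
import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings

from oracles import bh_definitional, fisher_p_enumeration
from traitphewas.stats import (
    Contingency2x2,
    StatsError,
    bh_fdr,
    fisher_exact,
    fisher_p,
    logistic_fit,
    sample_or_woolf,
    student_t,
)


class TestWoolf:
    def test_anemia_row_reproduces_published_interval(self):
        est = sample_or_woolf(Contingency2x2(31, 45, 94, 266))
        assert round(est.point, 1) == 1.9
        assert round(est.ci_low, 1) == 1.2
        assert round(est.ci_high, 1) == 3.3

    def test_hyperglycemia_row(self):
        est = sample_or_woolf(Contingency2x2(8, 51, 17, 269))
        assert round(est.point, 2) == 2.48
        assert round(est.ci_low, 1) == 1.0
        assert round(est.ci_high, 1) == 6.1

    def test_symmetric_table(self):
        est = sample_or_woolf(Contingency2x2(1, 1, 1, 1))
        assert est.point == pytest.approx(1.0)
        assert est.ci_low * est.ci_high == pytest.approx(1.0)

    def test_zero_cell_gets_haldane_correction(self):
        est = sample_or_woolf(Contingency2x2(0, 10, 5, 5))
        assert est.continuity_corrected
        assert 0 < est.ci_low < est.point < est.ci_high

    def test_negative_cell_rejected(self):
        with pytest.raises(StatsError):
            Contingency2x2(-1, 1, 1, 1)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(1, 40)] * 4), st.integers(2, 5))
    def test_or_invariant_under_transpose_and_row_scaling(self, cells, k):
        a, b, c, d = cells
        point = sample_or_woolf(Contingency2x2(a, b, c, d)).point
        transposed = sample_or_woolf(Contingency2x2(a, c, b, d)).point
        scaled = sample_or_woolf(Contingency2x2(k * a, k * b, c, d)).point
        assert point == pytest.approx(transposed)
        assert point == pytest.approx(scaled)

    def test_ci_coverage_at_table2_margins(self):
        """Woolf 95% CI covers a true OR of 2 in 92-98% of 500 draws."""
        rng = np.random.default_rng(2024)
        true_or = 2.0
        n_exp, n_cmp, p_cmp = 76, 366, 0.26
        p_exp = true_or * p_cmp / (1 - p_cmp + true_or * p_cmp)
        hits = 0
        for _ in range(500):
            a = rng.binomial(n_exp, p_exp)
            c = rng.binomial(n_cmp, p_cmp)
            est = sample_or_woolf(Contingency2x2(a, n_exp - a, c, n_cmp - c))
            hits += est.ci_low <= true_or <= est.ci_high
        assert 0.92 <= hits / 500 <= 0.98


class TestFisherExact:
    def test_efficacy_table_reproduces_published_estimate(self):
        res = fisher_exact(Contingency2x2(15, 34, 36, 239))
        assert res.estimate.point == pytest.approx(2.9166, abs=1e-3)
        assert res.estimate.ci_low == pytest.approx(1.3389, abs=1e-3)
        assert res.estimate.ci_high == pytest.approx(6.1691, abs=1e-3)
        assert res.p == pytest.approx(0.004576, abs=1e-5)

    def test_symmetric_table(self):
        res = fisher_exact(Contingency2x2(1, 1, 1, 1))
        assert res.p == pytest.approx(1.0)
        assert res.estimate.point == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_margins_flagged(self):
        res = fisher_exact(Contingency2x2(0, 0, 3, 7))
        assert res.p == 1.0
        assert res.estimate.degenerate
        assert math.isnan(res.estimate.point)

    def test_zero_cell_bounds(self):
        res = fisher_exact(Contingency2x2(0, 5, 3, 7))
        assert res.estimate.point == 0.0
        assert res.estimate.ci_low == 0.0
        assert res.estimate.ci_high > 0

    @settings(max_examples=80, deadline=None)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_p_matches_rational_enumeration(self, cells):
        a, b, c, d = cells
        table = Contingency2x2(a, b, c, d)
        if table.degenerate:
            return
        expected = float(fisher_p_enumeration(a, b, c, d))
        assert fisher_p(table) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_agrees_with_scipy(self):
        for cells in [(15, 34, 36, 239), (3, 9, 8, 2), (1, 0, 4, 6)]:
            table = Contingency2x2(*cells)
            res = fisher_exact(table)
            sp_p = scipy.stats.fisher_exact([[cells[0], cells[1]],
                                             [cells[2], cells[3]]]).pvalue
            assert res.p == pytest.approx(sp_p, rel=1e-8)
            sp_or = scipy.stats.contingency.odds_ratio(
                [[cells[0], cells[1]], [cells[2], cells[3]]], kind="conditional"
            )
            if np.isfinite(res.estimate.point) and res.estimate.point > 0:
                assert res.estimate.point == pytest.approx(
                    sp_or.statistic, rel=1e-4
                )
            ci = sp_or.confidence_interval(0.95)
            if res.estimate.ci_low > 0:
                assert res.estimate.ci_low == pytest.approx(ci.low, rel=1e-4)
            if math.isfinite(res.estimate.ci_high):
                assert res.estimate.ci_high == pytest.approx(ci.high, rel=1e-4)


class TestStudentT:
    def test_identical_samples(self):
        t, p = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_variance_unequal_means_is_an_error(self):
        with pytest.raises(StatsError):
            student_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])

    def test_matches_textbook_pooled_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1, 40)
        t, p = student_t(x, y)
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(
            2 * scipy.stats.t.sf(abs(t_hand), nx + ny - 2)
        )

    def test_power_at_half_sigma_shift(self):
        """N(0,1) vs N(0.5,1), n=50/arm: rejection rate ~0.70 at alpha 0.05."""
        rng = np.random.default_rng(11)
        rejections = sum(
            student_t(rng.normal(0, 1, 50), rng.normal(0.5, 1, 50))[1] < 0.05
            for _ in range(1000)
        )
        assert 0.60 < rejections / 1000 < 0.80


class TestLogistic:
    def test_saturated_2x2_equals_cross_product_or(self):
        a, b, c, d = 13, 17, 8, 29
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        design = np.column_stack([np.ones_like(x), x])
        fit = logistic_fit(design, y)
        woolf = sample_or_woolf(Contingency2x2(a, b, c, d))
        assert fit.odds_ratios[1] == pytest.approx(woolf.point, rel=1e-6)
        assert fit.ci_low[1] == pytest.approx(woolf.ci_low, rel=1e-6)
        assert fit.ci_high[1] == pytest.approx(woolf.ci_high, rel=1e-6)

    def test_all_zero_outcome_flags_separation(self):
        design = np.column_stack([np.ones(10), np.arange(10)])
        fit = logistic_fit(design, np.zeros(10))
        assert fit.separation

    def test_adjusted_recovery_simulation(self):
        """True exposure log-OR 0.7 with one confounder: Wald CI covers it
        in >=90 of 100 seeded replicates at n=5000."""
        rng = np.random.default_rng(42)
        hits = 0
        n = 5000
        for _ in range(100):
            conf = rng.normal(size=n)
            expo = (rng.random(n) < 1 / (1 + np.exp(-conf))).astype(float)
            logit = -1.0 + 0.7 * expo + 0.5 * conf
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            design = np.column_stack([np.ones(n), expo, conf])
            fit = logistic_fit(design, y)
            hits += fit.ci_low[1] <= math.exp(0.7) <= fit.ci_high[1]
        assert hits >= 90


class TestBhFdr:
    def test_worked_example(self):
        flags, threshold = bh_fdr([0.001, 0.01, 0.03, 0.04, 0.5], q=0.2)
        assert flags.tolist() == [True, True, True, True, False]
        assert threshold == 0.04

    def test_all_equal_p_at_top_rank(self):
        flags, _ = bh_fdr([0.01] * 10, q=0.2)
        assert flags.all()

    def test_empty_input(self):
        flags, threshold = bh_fdr([], q=0.2)
        assert len(flags) == 0
        assert threshold == 0.0

    def test_monotone_in_q(self):
        rng = np.random.default_rng(3)
        p = rng.random(50) ** 2
        narrow, _ = bh_fdr(p, q=0.1)
        wide, _ = bh_fdr(p, q=0.2)
        assert (wide | ~narrow).all()  # narrow set is a subset

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            flags, _ = bh_fdr(p, q=0.2)
            sm_flags = multipletests(p, alpha=0.2, method="fdr_bh")[0]
            assert (flags == sm_flags).all()

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = (rng.random(rng.integers(1, 40)) ** rng.uniform(0.5, 3)).tolist()
            flags, threshold = bh_fdr(p, q=0.2)
            oflags, othreshold = bh_definitional(p, 0.2)
            assert flags.tolist() == oflags
            assert threshold == pytest.approx(othreshold)
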