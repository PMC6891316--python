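import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

from fatiguenet import (
    StudyTable, ValidationError, compare_conditions, critical_t,
    error_rate_summary, stage_trend, t_test,
)


def make_table(values_by_condition, column="C", n_subjects=4, jitter=0.0,
               seed=0):
    """Study table whose `column` follows per-stage values per condition."""
    rng = np.random.default_rng(seed)
    t = StudyTable()
    for s in range(n_subjects):
        for cond, vals in values_by_condition.items():
            for stage, v in enumerate(vals, start=1):
                row = {c: 0.0 for c in ("C", "G", "power_ratio", "eye_rate",
                                        "error_rate")}
                row["sq_score"] = 4
                row[column] = v + jitter * rng.standard_normal()
                t.add_row(f"S{s:02d}", cond, stage, **row)
    return t


class TestTTest:
    def test_identical_samples(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and not res.significant

    def test_pooled_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        sp2 = ((4 * a.var(ddof=1) + 4 * b.var(ddof=1)) / 8)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        res = t_test(a, b, design="independent_pooled")
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.df == 8

    def test_swap_negates_t_keeps_p(self, rng):
        a, b = rng.standard_normal(8), 0.5 + rng.standard_normal(8)
        r1, r2 = t_test(a, b), t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_significance_iff_t_exceeds_critical(self, rng):
        for _ in range(20):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6) + rng.uniform(-2, 2)
            res = t_test(a, b)
            assert res.significant == (abs(res.t) > res.t_crit)

    def test_paired_design(self, rng):
        a = rng.standard_normal(10)
        b = a + 0.5 + 0.1 * rng.standard_normal(10)
        res = t_test(a, b, design="paired")
        assert res.df == 9
        assert res.significant

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            t_test([1, 2, 3], [1, 2], design="paired")

    def test_degenerate_zero_variance_unequal_means(self):
        res = t_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.degenerate
        assert res.p == 0.0

    def test_type_one_error_rate_near_alpha(self):
        # null calibration: rejection rate over 500 replicates within a
        # 3-sigma binomial band around 0.05
        rng = np.random.default_rng(99)
        n_rep = 500
        rejections = sum(
            t_test(rng.standard_normal(10), rng.standard_normal(10)).significant
            for _ in range(n_rep))
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < band


class TestCriticalT:
    @pytest.mark.parametrize("df,expected", [
        (6, 2.447), (12, 2.179), (18, 2.101), (22, 2.074)])
    def test_printed_values(self, df, expected):
        assert critical_t(0.05, df) == pytest.approx(expected, abs=5e-4)

    def test_normal_limit(self):
        assert critical_t(0.05, 10 ** 6) == pytest.approx(1.960, abs=2e-3)

    def test_quadrature_oracle(self):
        # integrate the t density directly and bisect for the quantile
        def t_pdf(x, df):
            c = special.gamma((df + 1) / 2) / (
                np.sqrt(df * np.pi) * special.gamma(df / 2))
            return c * (1 + x ** 2 / df) ** (-(df + 1) / 2)

        for df in (1, 2, 5, 12, 30, 100):
            target = 0.975
            lo, hi = 0.0, 700.0
            for _ in range(60):
                mid = (lo + hi) / 2
                mass = 0.5 + integrate.quad(t_pdf, 0, mid, args=(df,))[0]
                if mass < target:
                    lo = mid
                else:
                    hi = mid
            assert critical_t(0.05, df) == pytest.approx((lo + hi) / 2,
                                                         abs=1e-4)

    @pytest.mark.parametrize("alpha,df", [(0.0, 5), (1.0, 5), (0.05, 0)])
    def test_invalid_inputs_rejected(self, alpha, df):
        with pytest.raises(ValidationError):
            critical_t(alpha, df)


class TestStageTrend:
    def test_strictly_increasing_means(self):
        t = make_table({"normal": [1, 2, 3, 4, 5, 6, 7]})
        tr = stage_trend(t, "C", "normal")
        assert tr.spearman_rho == pytest.approx(1.0)
        np.testing.assert_allclose(tr.means, np.arange(1, 8))

    def test_constant_column_flagged(self):
        t = make_table({"normal": [2, 2, 2, 2, 2, 2, 2]})
        tr = stage_trend(t, "C", "normal")
        assert tr.tie_degenerate and tr.spearman_rho == 0.0

    def test_missing_stage_listed(self):
        t = make_table({"normal": [1, 2, 3, 4, 5, 6, 7]})
        t.data = t.data[t.data["stage"] != 4]
        with pytest.raises(ValidationError, match=r"\[4\]"):
            stage_trend(StudyTable(t.data), "C", "normal")

    def test_strong_trend_beats_permutation(self, rng):
        # permutation oracle: shuffled stage labels rarely reach the
        # observed correlation for a strong injected trend
        t = make_table({"normal": [1, 2, 3, 4, 5, 6, 7]}, jitter=0.3, seed=3)
        obs = abs(stage_trend(t, "C", "normal").spearman_rho)
        from scipy.stats import spearmanr
        means = stage_trend(t, "C", "normal").means
        exceed = 0
        for _ in range(500):
            perm = rng.permutation(7)
            if abs(spearmanr(np.arange(7), means[perm]).statistic) >= obs:
                exceed += 1
        assert exceed / 500 < 0.05


class TestCompareConditions:
    def test_identical_conditions_not_significant(self):
        vals = [1, 2, 3, 4, 5, 6, 7]
        t = make_table({"normal": vals, "mrm": vals})
        cc = compare_conditions(t, "C")
        assert cc.result.t == 0.0 and not cc.result.significant
        np.testing.assert_allclose(cc.stage_deltas, 0.0)

    def test_df_matches_stage_mean_design(self):
        t = make_table({"normal": [1, 2, 3, 4, 5, 6, 7],
                        "mrm": [1, 1, 2, 2, 3, 3, 4]}, jitter=0.1)
        cc = compare_conditions(t, "C")
        assert cc.result.df == 7 + 7 - 2 == 12

    def test_missing_condition_rejected(self):
        t = make_table({"normal": [1, 2, 3, 4, 5, 6, 7]})
        with pytest.raises(ValidationError):
            compare_conditions(t, "C")


class TestErrorRateSummary:
    def test_arithmetic(self):
        df = pd.DataFrame({
            "stage": [1, 2], "correct": [30, 20],
            "incorrect": [0, 3], "timeout": [0, 2]})
        rates = error_rate_summary(df)
        assert rates[1] == 0.0
        assert rates[2] == pytest.approx(0.2)

    def test_zero_total_flagged_undefined(self):
        df = pd.DataFrame({"stage": [1], "correct": [0],
                           "incorrect": [0], "timeout": [0]})
        assert np.isnan(error_rate_summary(df)[1])

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"stage": [1], "correct": [-1],
                           "incorrect": [0], "timeout": [0]})
        with pytest.raises(ValidationError):
            error_rate_summary(df)

    def test_binomial_simulation_recovers_rate(self, rng):
        p, n = 0.15, 100
        errs = rng.binomial(n, p)
        df = pd.DataFrame({"stage": [1], "correct": [n - errs],
                           "incorrect": [errs], "timeout": [0]})
        est = error_rate_summary(df)[1]
        ci = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(est - p) <= ci + 1e-9
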