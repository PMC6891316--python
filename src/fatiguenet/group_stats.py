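"""Two-tailed t-tests, critical values, and stage/condition summaries.

Every comparison in the pipeline is a two-tailed Student t-test at
alpha = 0.05 by default.  The default design is the independent
pooled-variance test: comparing the 7 per-stage means of two driving modes
gives df = 7 + 7 - 2 = 12, matching the degrees of freedom the stage-mean
mode comparisons report.  Paired and Welch variants are available.
No multiple-testing correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_signals import StudyTable, ValidationError

DESIGNS = ("independent_pooled", "independent_welch", "paired")


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    t_crit: float
    significant: bool
    design: str
    alpha: float = 0.05
    degenerate: bool = False  # zero variance with unequal means


def critical_t(alpha: float, df: float) -> float:
    """Two-tailed critical value: the (1 - alpha/2) quantile of t(df)."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    return float(sps.t.ppf(1.0 - alpha / 2.0, df))


def t_test(sample_a, sample_b, design: str = "independent_pooled",
           alpha: float = 0.05) -> TestResult:
    """Two-tailed t-test between two samples.

    Degenerate inputs (zero variance in both samples) give t = 0, p = 1
    when the means agree and a flagged result with infinite |t|, p = 0
    otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if design not in DESIGNS:
        raise ValidationError(f"design must be one of {DESIGNS}")
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    if design == "paired" and a.size != b.size:
        raise ValidationError("paired design requires equal-length samples")

    if design == "paired":
        df = a.size - 1
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                t, p, degen = 0.0, 1.0, False
            else:
                t, p, degen = np.inf * np.sign(d.mean()), 0.0, True
        else:
            t, p = sps.ttest_rel(a, b)
            degen = False
    else:
        equal_var = design == "independent_pooled"
        var_a, var_b = a.var(ddof=1), b.var(ddof=1)
        if var_a == 0.0 and var_b == 0.0:
            df = a.size + b.size - 2 if equal_var else a.size + b.size - 2
            if np.isclose(a.mean(), b.mean()):
                t, p, degen = 0.0, 1.0, False
            else:
                t, p, degen = np.inf * np.sign(a.mean() - b.mean()), 0.0, True
        else:
            with warnings.catch_warnings():
                # near-constant samples trip scipy's precision-loss warning;
                # the exact-constant case is already handled above
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.ttest_ind(a, b, equal_var=equal_var)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
            degen = False
        if equal_var:
            df = a.size + b.size - 2

    t_crit = critical_t(alpha, df if np.isfinite(df) and df >= 1 else 1)
    return TestResult(t=float(t), df=float(df), p=float(p), t_crit=t_crit,
                      significant=bool(p < alpha), design=design, alpha=alpha,
                      degenerate=degen)


@dataclass
class TrendResult:
    stages: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    spearman_rho: float
    tie_degenerate: bool


def stage_trend(table: StudyTable, column: str, condition: str) -> TrendResult:
    """Per-stage means/SDs of a StudyTable column plus a monotone-trend
    statistic (Spearman rho of stage vs per-stage mean)."""
    df = table.data[table.data["condition"] == condition]
    if df.empty:
        raise ValidationError(f"no rows for condition {condition!r}")
    stages = np.sort(df["stage"].unique())
    expected = np.arange(1, 8)
    missing = sorted(int(s) for s in set(expected) - set(stages))
    if missing:
        raise ValidationError(f"missing stage(s) {missing} for {condition!r}")
    grouped = df.groupby("stage")[column]
    means = grouped.mean().reindex(expected).to_numpy()
    sds = grouped.std(ddof=1).reindex(expected).to_numpy()
    if np.allclose(means, means[0]):
        rho, tie = 0.0, True
    else:
        rho = float(sps.spearmanr(expected, means).statistic)
        tie = False
    return TrendResult(stages=expected, means=means, sds=sds,
                       spearman_rho=rho, tie_degenerate=tie)


@dataclass
class ConditionComparison:
    result: TestResult
    stage_deltas: np.ndarray  # normal minus mrm, per stage


def compare_conditions(table: StudyTable, column: str,
                       design: str = "independent_pooled",
                       alpha: float = 0.05) -> ConditionComparison:
    """Compare the two driving modes on one metric.

    The default follows the stage-mean design: the 7 per-stage means (over
    subjects) of each condition are the two samples, pooled-variance t-test,
    df = 12.
    """
    present = set(table.data["condition"].unique())
    if present != {"normal", "mrm"}:
        raise ValidationError(f"need both conditions, found {sorted(present)}")
    means = {}
    for cond in ("normal", "mrm"):
        means[cond] = stage_trend(table, column, cond).means
    res = t_test(means["normal"], means["mrm"], design=design, alpha=alpha)
    return ConditionComparison(result=res,
                               stage_deltas=means["normal"] - means["mrm"])


def error_rate_summary(responses: pd.DataFrame) -> pd.Series:
    """Per-stage response error proportion.

    ``responses`` has columns ``stage, correct, incorrect, timeout``;
    timeouts count as errors.  Stages with zero recorded responses yield
    NaN (flagged undefined) rather than raising.
    """
    for col in ("stage", "correct", "incorrect", "timeout"):
        if col not in responses.columns:
            raise ValidationError(f"responses table missing column {col!r}")
    if (responses[["correct", "incorrect", "timeout"]] < 0).any().any():
        raise ValidationError("response counts must be non-negative")
    g = responses.groupby("stage")[["correct", "incorrect", "timeout"]].sum()
    total = g.sum(axis=1)
    errors = g["incorrect"] + g["timeout"]
    with np.errstate(invalid="ignore"):
        rate = errors / total.replace(0, np.nan)
    return rate
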