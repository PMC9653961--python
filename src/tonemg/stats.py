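"""Two-group comparison and test-retest reliability statistics.

Group differences use Student's two-sample t (pooled variance by default,
Welch behind a flag) for numerical data and the chi-squared test for nominal
data; effect sizes are pooled-SD Cohen's d, reported as magnitudes with the
direction kept as metadata.  Test-retest reliability across the three
repeated trials is measured by the intraclass correlation coefficient
(two-way, absolute-agreement, single-measure by default) and the cross-trial
standard deviation.  No multiple-testing correction is applied; p-values are
annotated with the conventional 0.05 / 0.01 / 0.001 stars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "ReliabilityResult",
    "cohens_d",
    "students_t",
    "chi_squared",
    "icc",
    "significance_stars",
    "build_comparison_report",
    "build_reliability_report",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_samples(cls, label: str, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        return cls(label, x.size, float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0)


@dataclass
class GroupComparison:
    feature: str
    summary1: GroupSummary
    summary2: GroupSummary
    t_statistic: float
    p_value: float
    df: float
    cohens_d: float
    direction: int  # sign of (mean2 - mean1)
    stars: str = ""


@dataclass
class ReliabilityResult:
    feature: str
    icc: float
    icc_model: str
    cross_trial_sd: float
    n_subjects: int
    n_trials: int
    flags: tuple[str, ...] = ()


@dataclass
class EffectSize:
    d: float  # magnitude
    direction: int  # sign of (mean2 - mean1)
    infinite: bool = False

    def __float__(self) -> float:
        return self.d


def cohens_d(m1, s1, n1, m2, s2, n2) -> EffectSize:
    """Pooled-SD Cohen's d from group summary statistics.

    d = |m2 - m1| / s_p with s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2)/(n1+n2-2).
    The magnitude is reported; the sign of (m2 - m1) rides along as
    ``direction``.  A zero pooled SD with unequal means sets ``infinite``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d needs n >= 2 in each group")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    diff = m2 - m1
    direction = int(np.sign(diff))
    if sp == 0:
        if diff == 0:
            return EffectSize(0.0, 0)
        return EffectSize(np.inf, direction, infinite=True)
    return EffectSize(abs(diff) / sp, direction)


def students_t(x1, x2, welch: bool = False, alternative: str = "two-sided"):
    """Two-sample t-test from raw samples or :class:`GroupSummary` pairs.

    Returns ``(t, p, df)``.  Default is the pooled-variance two-sided test;
    ``welch=True`` drops the equal-variance assumption, ``alternative``
    passes through to one-sided variants.
    """
    if isinstance(x1, GroupSummary) != isinstance(x2, GroupSummary):
        raise TypeError("pass two sample arrays or two GroupSummary objects")
    if isinstance(x1, GroupSummary):
        if x1.n < 2 or x2.n < 2:
            raise ValueError("t-test needs n >= 2 in each group")
        res = ss.ttest_ind_from_stats(
            x1.mean, x1.sd, x1.n, x2.mean, x2.sd, x2.n,
            equal_var=not welch, alternative=alternative,
        )
        n1, n2, v1, v2 = x1.n, x2.n, x1.sd**2, x2.sd**2
    else:
        a = np.asarray(x1, dtype=float)
        b = np.asarray(x2, dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs n >= 2 in each group")
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            # degenerate but well-defined: identical constant groups
            return 0.0, 1.0, float(a.size + b.size - 2)
        res = ss.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
        n1, n2, v1, v2 = a.size, b.size, a.var(ddof=1), b.var(ddof=1)
    if not welch:
        df = float(n1 + n2 - 2)
    else:
        df = float(
            (v1 / n1 + v2 / n2) ** 2
            / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        )
    return float(res.statistic), float(res.pvalue), df


def chi_squared(table, correction: bool = False):
    """Pearson chi-squared on a 2 x k contingency table.

    Returns ``(statistic, p, expected)``; ``correction`` applies the Yates
    continuity correction (2 x 2 only).  Expected counts below 5 trigger a
    small-cell warning.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 columns")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    stat, p, _, expected = ss.chi2_contingency(table, correction=correction)
    if np.any(expected < 5):
        warnings.warn("expected count below 5; chi-squared approximation is weak",
                      stacklevel=2)
    return float(stat), float(p), expected


def icc(trials, model: str = "ICC(A,1)", feature: str = "") -> ReliabilityResult:
    """Intraclass correlation and cross-trial SD for a subjects x trials matrix.

    ``model`` is ``"ICC(A,1)"`` (two-way, absolute agreement, single
    measurement; default) or ``"ICC(3,1)"`` (two-way mixed, consistency).
    Rows with missing cells are dropped (logged).  The cross-trial SD is the
    mean over subjects of the within-subject SD across trials.
    """
    if model not in ("ICC(A,1)", "ICC(3,1)"):
        raise ValueError(f"unknown ICC model {model!r}")
    m = np.asarray(trials, dtype=float)
    if m.ndim != 2:
        raise ValueError("trials must be a 2-D subjects x trials matrix")
    complete = np.isfinite(m).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} subject(s) with missing trials",
                      stacklevel=2)
    m = m[complete]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 complete subjects and >= 2 trials")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    rows_constant = np.ptp(m, axis=1) == 0  # exact within-subject constancy
    ss_rows = k * np.sum((row_means - grand) ** 2)
    if rows_constant.all():
        ss_cols = 0.0
        ss_err = 0.0
    else:
        ss_cols = n * np.sum((col_means - grand) ** 2)
        ss_err = max(np.sum((m - grand) ** 2) - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    flags = []
    if msr == 0:
        flags.append("zero_between_subject_variance")
        value = np.nan
    elif model == "ICC(A,1)":
        value = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    else:
        value = (msr - mse) / (msr + (k - 1) * mse)
    row_sds = np.where(rows_constant, 0.0, m.std(axis=1, ddof=1))
    cross_sd = float(row_sds.mean())
    return ReliabilityResult(
        feature=feature,
        icc=float(value),
        icc_model=model,
        cross_trial_sd=cross_sd,
        n_subjects=n,
        n_trials=k,
        flags=tuple(flags),
    )


def significance_stars(p: float) -> str:
    """Footnote convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def build_comparison_report(
    features: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("CT+", "CT-"),
    value_col: str = "value",
    welch: bool = False,
) -> pd.DataFrame:
    """Table-shaped two-group comparison: one row per tone x feature.

    ``features`` is long-format with columns subject_id, group, tone,
    feature, value (one row per subject, i.e. trial-averaged).  Listwise
    deletion is applied per feature; a group with fewer than two complete
    subjects for a feature raises.
    """
    required = {"subject_id", group_col, "tone", "feature", value_col}
    if not required.issubset(features.columns):
        raise ValueError(f"features table must have columns {sorted(required)}")
    rows = []
    for (tone, feat), sub in features.groupby(["tone", "feature"], sort=True):
        x1 = sub.loc[sub[group_col] == groups[0], value_col].dropna().to_numpy()
        x2 = sub.loc[sub[group_col] == groups[1], value_col].dropna().to_numpy()
        if x1.size < 2 or x2.size < 2:
            raise ValueError(
                f"group with n < 2 for tone {tone} feature {feat!r}"
            )
        s1 = GroupSummary.from_samples(groups[0], x1)
        s2 = GroupSummary.from_samples(groups[1], x2)
        t, p, df = students_t(x1, x2, welch=welch)
        d = cohens_d(s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n)
        rows.append(
            {
                "tone": tone,
                "feature": feat,
                "n_1": s1.n,
                "mean_1": s1.mean,
                "sd_1": s1.sd,
                "n_2": s2.n,
                "mean_2": s2.mean,
                "sd_2": s2.sd,
                "t": t,
                "df": df,
                "p": p,
                "cohens_d": d.d,
                "direction": d.direction,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def build_reliability_report(
    trials: pd.DataFrame,
    model: str = "ICC(A,1)",
    value_col: str = "value",
) -> pd.DataFrame:
    """Per tone x feature ICC and cross-trial SD from a long trials table.

    ``trials`` has columns subject_id, tone, feature, trial, value.
    """
    required = {"subject_id", "tone", "feature", "trial", value_col}
    if not required.issubset(trials.columns):
        raise ValueError(f"trials table must have columns {sorted(required)}")
    rows = []
    for (tone, feat), sub in trials.groupby(["tone", "feature"], sort=True):
        wide = sub.pivot_table(
            index="subject_id", columns="trial", values=value_col, aggfunc="first"
        )
        res = icc(wide.to_numpy(), model=model, feature=feat)
        pooled = sub.groupby("subject_id")[value_col].mean()
        rows.append(
            {
                "tone": tone,
                "feature": feat,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)),
                "cross_trial_sd": res.cross_trial_sd,
                "icc": res.icc,
                "icc_model": res.icc_model,
                "n_subjects": res.n_subjects,
                "n_trials": res.n_trials,
            }
        )
    return pd.DataFrame(rows)
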