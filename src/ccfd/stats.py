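"""Inferential layer for the 2 (group) × 2 (timepoint) cohort design.

Implements the study's statistics: one-sample Kolmogorov–Smirnov normality
screening, two-sided unpaired t-tests at baseline, a balanced mixed-design
(repeated-measures) two-way ANOVA with the group × time interaction, the
nested-model F-tests comparing linear-regression slopes and intercepts,
and the percent-change helper.

No multiple-testing correction is applied anywhere; the design reports raw
per-comparison p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUPS = ("RPD", "control")
TIMEPOINTS = ("baseline", "follow_up")


class ZeroVarianceError(ValueError):
    """Raised when a test is requested on constant data."""


class DegenerateDataError(ValueError):
    """Raised when an error term is identically zero and F is undefined."""


@dataclass(frozen=True)
class RmAnovaResult:
    """F and p for the interaction, within-subject time and between-subject
    group effects of the balanced 2 × 2 mixed design.

    ``time_effect_reportable`` flags the study's reporting convention: the
    within-group time effect is interpreted only when no between-group
    difference (interaction or group main effect) is detected at α = 0.05.
    The flag changes nothing computationally.
    """

    interaction_f: float
    interaction_p: float
    time_f: float
    time_p: float
    group_f: float
    group_p: float
    n_per_group: int
    time_effect_reportable: bool


@dataclass(frozen=True)
class SlopeComparisonResult:
    f_value: float
    p_value: float
    df_num: int
    df_den: int
    comparison_kind: str  # "slopes" or "intercepts"


def ks_normality(values) -> float:
    """One-sample KS p-value against a normal with the sample's mean and SD.

    Parameters are estimated from the data, so this is the common software
    default rather than a strict Lilliefors-corrected test; the p-value is
    therefore conservative as a normality screen.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("constant sample: normality test undefined")
    return float(sps.kstest(v, sps.norm(loc=v.mean(), scale=sd).cdf).pvalue)


def unpaired_t_test(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided unpaired t-test; pooled-variance Student by default,
    Welch via ``equal_var=False``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _cell_matrix(table: pd.DataFrame, metric: str | None, roi_kind: str | None):
    """Pivot the long table into per-group (n, 2) value matrices ordered
    baseline, follow-up; validates balance and completeness."""
    df = table
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    if roi_kind is not None and "roi_kind" in df.columns:
        df = df[df["roi_kind"] == roi_kind]
    if df.empty:
        raise ValueError(f"no records for metric={metric!r}, roi={roi_kind!r}")
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    mats = {}
    for g in groups:
        sub = df[df["group"] == g]
        wide = sub.pivot_table(
            index="subject_id", columns="timepoint", values="value", aggfunc="first"
        )
        missing = [t for t in TIMEPOINTS if t not in wide.columns]
        if missing or wide[list(TIMEPOINTS)].isna().any().any():
            raise ValueError(f"group {g!r}: incomplete baseline/follow-up pairs")
        mats[g] = wide[list(TIMEPOINTS)].to_numpy(dtype=float)
    n0, n1 = (mats[g].shape[0] for g in groups)
    if n0 != n1:
        raise ValueError(f"unbalanced groups: {n0} vs {n1} subjects")
    if n0 < 2:
        raise ValueError("need at least 2 subjects per group")
    return groups, mats


def rm_anova_2x2(
    table: pd.DataFrame,
    metric: str | None = None,
    roi_kind: str | None = None,
    alpha: float = 0.05,
) -> RmAnovaResult:
    """Balanced 2 × 2 mixed ANOVA: group between subjects, time within.

    Sums of squares follow the standard cell-means decomposition; the group
    main effect is tested against the between-subject error
    (subjects within groups), time and the group × time interaction against
    the within-subject error, each with 2(n−1) denominator df.
    """
    groups, mats = _cell_matrix(table, metric, roi_kind)
    return rm_anova_from_matrices(mats[groups[0]], mats[groups[1]], alpha=alpha)


def rm_anova_from_matrices(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> RmAnovaResult:
    """Balanced 2 × 2 mixed ANOVA from two (n, 2) value matrices ordered
    (baseline, follow-up); the matrix-level core behind :func:`rm_anova_2x2`."""
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if group_a.shape != group_b.shape or group_a.ndim != 2 or group_a.shape[1] != 2:
        raise ValueError("need two equal-shape (n, 2) matrices")
    if group_a.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    data = np.stack([group_a, group_b])  # (2 groups, n, 2 times)
    n = data.shape[1]
    grand = data.mean()
    subj_means = data.mean(axis=2)  # (2, n)
    group_means = data.mean(axis=(1, 2))  # (2,)
    time_means = data.mean(axis=(0, 1))  # (2,)
    cell_means = data.mean(axis=1)  # (2, 2)

    ss_between_subj = 2.0 * ((subj_means - grand) ** 2).sum()
    ss_group = 2.0 * n * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_time = 2.0 * n * ((time_means - grand) ** 2).sum()
    ss_inter = n * (
        (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
    ).sum()
    ss_within = ((data - subj_means[:, :, None]) ** 2).sum()
    ss_err_within = ss_within - ss_time - ss_inter

    df_err = 2 * (n - 1)
    ss_total = float(((data - grand) ** 2).sum())
    if ss_total == 0.0:
        raise DegenerateDataError("all values equal: F ratios undefined")
    tol = 1e-12 * ss_total
    ss_subj_within = 0.0 if ss_subj_within <= tol else ss_subj_within
    ss_err_within = 0.0 if ss_err_within <= tol else ss_err_within

    def f_p(ss_effect: float, ss_error: float) -> tuple[float, float]:
        # noiseless constructed designs can have an exactly-zero error term
        if ss_effect <= tol:
            return 0.0, 1.0
        if ss_error == 0.0:
            return float("inf"), 0.0
        f = ss_effect / (ss_error / df_err)
        return float(f), float(sps.f.sf(f, 1, df_err))

    group_f, group_p = f_p(ss_group, ss_subj_within)
    inter_f, inter_p = f_p(ss_inter, ss_err_within)
    time_f, time_p = f_p(ss_time, ss_err_within)
    return RmAnovaResult(
        interaction_f=inter_f,
        interaction_p=inter_p,
        time_f=time_f,
        time_p=time_p,
        group_f=group_f,
        group_p=group_p,
        n_per_group=n,
        time_effect_reportable=(inter_p >= alpha and group_p >= alpha),
    )


def _line_rss(x: np.ndarray, y: np.ndarray) -> float:
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    return float(syy - sxy * sxy / sxx)


def compare_regressions(
    x1, y1, x2, y2
) -> tuple[SlopeComparisonResult, SlopeComparisonResult]:
    """Nested-model F-tests for equal slopes and equal intercepts.

    The slope test contrasts two separate lines (4 parameters) with a
    common-slope model (3 parameters), F on (1, n1+n2−4) df.  The intercept
    test contrasts the common-slope model with a single pooled line
    (2 parameters), F on (1, n1+n2−3) df; it is reported regardless of the
    slope outcome but is only interpretable when slopes are compatible.
    Degenerate residuals are resolved as F = 0, p = 1 when the extra
    parameters buy nothing and F = ∞, p = 0 for a perfect-fit improvement.
    """
    x1, y1, x2, y2 = (np.asarray(v, dtype=float) for v in (x1, y1, x2, y2))
    for x, y in ((x1, y1), (x2, y2)):
        if x.size != y.size:
            raise ValueError("x and y lengths differ")
        if x.size < 3:
            raise ValueError("each dataset needs at least 3 points")
        if np.ptp(x) == 0:
            raise ValueError("zero x variance: slope undefined")
    n = x1.size + x2.size

    rss_sep = _line_rss(x1, y1) + _line_rss(x2, y2)

    # common slope, separate intercepts: pooled within-dataset slope
    sxx = sum(((x - x.mean()) ** 2).sum() for x in (x1, x2))
    sxy = sum(
        ((x - x.mean()) * (y - y.mean())).sum() for x, y in ((x1, y1), (x2, y2))
    )
    b = sxy / sxx
    rss_common = float(
        sum(
            ((y - y.mean()) - b * (x - x.mean())).dot((y - y.mean()) - b * (x - x.mean()))
            for x, y in ((x1, y1), (x2, y2))
        )
    )
    rss_single = _line_rss(np.concatenate([x1, x2]), np.concatenate([y1, y2]))

    def nested_f(rss_reduced, rss_full, df_den, kind):
        num = max(rss_reduced - rss_full, 0.0)
        scale = max(rss_reduced, rss_full, 1.0)
        if num <= 1e-12 * scale:
            num = 0.0
        if rss_full <= 1e-12 * scale:
            if num == 0.0:
                f, p = 0.0, 1.0
            else:
                f, p = float("inf"), 0.0
        else:
            f = num / (rss_full / df_den)
            p = float(sps.f.sf(f, 1, df_den))
        return SlopeComparisonResult(
            f_value=float(f), p_value=float(p), df_num=1, df_den=df_den,
            comparison_kind=kind,
        )

    slopes = nested_f(rss_common, rss_sep, n - 4, "slopes")
    intercepts = nested_f(rss_single, rss_common, n - 3, "intercepts")
    return slopes, intercepts


def percent_change(baseline: float, follow_up: float) -> float:
    """100 × (follow_up − baseline) / baseline; baseline must be positive."""
    if not baseline > 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (follow_up - baseline) / baseline
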