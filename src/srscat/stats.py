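"""Score-comparison battery: effect sizes, ROC/AUC with statistical AUC
comparison, cut-off metrics, Bland-Altman agreement, and grouped descriptives.

Conventions: higher score = more autism-related traits = "positive" for ROC;
AUC is the tie-corrected rank (Mann-Whitney) estimator and its variance comes
from the placement-value (DeLong) decomposition, so two AUCs can be compared
with a 1-df chi-squared statistic, unpaired across randomized arms or paired
within person.  Bland-Altman limits use mean +/- 2 SD of the paired
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata
from sklearn.metrics import roc_curve

from .errors import ClassMissingError, SrsCatError, UndefinedEffectError

__all__ = [
    "ROCResult",
    "AUCComparison",
    "BlandAltmanResult",
    "cohens_d",
    "roc_auc",
    "compare_auc",
    "cutoff_metrics",
    "bland_altman",
    "descriptive_table",
    "density_shift_summary",
]


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD, pooling the
    two sample variances with n-1 weights."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SrsCatError("cohens_d requires at least 2 observations per group")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var <= 0:
        raise UndefinedEffectError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_variance: float
    n_cases: int
    n_controls: int
    # placement values, kept for paired AUC comparison (aligned to the input
    # order of cases / controls respectively)
    case_placements: np.ndarray = None
    control_placements: np.ndarray = None


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: V10 per case (fraction of controls it beats,
    ties half) and V01 per control."""
    x, y = scores[labels], scores[~labels]
    m, n = x.size, y.size
    r_all = rankdata(np.concatenate([x, y]))
    v10 = (r_all[:m] - rankdata(x)) / n
    v01 = 1.0 - (r_all[m:] - rankdata(y)) / m
    return v10, v01


def roc_auc(scores, labels) -> ROCResult:
    """ROC analysis of ``scores`` against binary case labels.

    AUC is the tie-corrected rank estimator P(case > control) + 1/2 P(tie);
    its variance is var(V10)/m + var(V01)/n from the placement decomposition.
    The full threshold sweep (sensitivity/specificity) is included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise SrsCatError("scores and labels must align")
    m, n = int(labels.sum()), int((~labels).sum())
    if m == 0 or n == 0:
        raise ClassMissingError("need both cases and controls for ROC analysis")
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = float(
        (np.var(v10, ddof=1) / m if m > 1 else 0.0)
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    )
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=auc,
        auc_variance=var,
        n_cases=m,
        n_controls=n,
        case_placements=v10,
        control_placements=v01,
    )


@dataclass(frozen=True)
class AUCComparison:
    chi_square: float
    df: int
    p_value: float
    auc_difference: float


def compare_auc(
    roc_a: ROCResult, roc_b: ROCResult, paired: bool = False
) -> AUCComparison:
    """Chi-squared (1 df) test of AUC_a = AUC_b.

    Unpaired (randomized arms): the variance of the difference is the sum of
    the two AUC variances.  Paired (both scores on the same respondents, same
    input order): the placement covariances are subtracted, which requires
    both ROCs to carry placements for identical case/control counts.
    """
    d = roc_a.auc - roc_b.auc
    if paired:
        if (
            roc_a.case_placements is None
            or roc_b.case_placements is None
            or roc_a.n_cases != roc_b.n_cases
            or roc_a.n_controls != roc_b.n_controls
        ):
            raise SrsCatError(
                "paired comparison needs both ROCs computed on the same "
                "respondents in the same order"
            )
        m, n = roc_a.n_cases, roc_a.n_controls
        var = 0.0
        if m > 1:
            var += (
                np.var(roc_a.case_placements, ddof=1)
                + np.var(roc_b.case_placements, ddof=1)
                - 2 * np.cov(roc_a.case_placements, roc_b.case_placements, ddof=1)[0, 1]
            ) / m
        if n > 1:
            var += (
                np.var(roc_a.control_placements, ddof=1)
                + np.var(roc_b.control_placements, ddof=1)
                - 2
                * np.cov(
                    roc_a.control_placements, roc_b.control_placements, ddof=1
                )[0, 1]
            ) / n
    else:
        var = roc_a.auc_variance + roc_b.auc_variance
    if var <= 0:
        if d == 0:
            return AUCComparison(0.0, 1, 1.0, 0.0)
        raise SrsCatError("zero variance with unequal AUCs; cannot form the test")
    stat = d * d / var
    return AUCComparison(float(stat), 1, float(chi2.sf(stat, 1)), float(d))


def cutoff_metrics(roc: ROCResult) -> tuple[pd.DataFrame, float]:
    """Per-threshold sensitivity/specificity table and the Youden-optimal
    cutoff (max sensitivity + specificity - 1; ties -> lower cutoff)."""
    table = pd.DataFrame(
        {
            "cutoff": roc.thresholds,
            "sensitivity": roc.sensitivities,
            "specificity": roc.specificities,
        }
    )
    table["youden_j"] = table["sensitivity"] + table["specificity"] - 1.0
    finite = table[np.isfinite(table["cutoff"])]
    best_j = finite["youden_j"].max()
    ties = finite[np.isclose(finite["youden_j"], best_j)]
    optimal = float(ties["cutoff"].min())
    return table, optimal


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    limits: tuple[float, float]
    pct_within: float
    n: int


def bland_altman(paired_a, paired_b) -> BlandAltmanResult:
    """Agreement of two paired measurements via differences a - b.

    Limits of agreement are mean +/- 2 SD of the differences; ``pct_within``
    is the percentage of pairs strictly inside the limits.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise SrsCatError("paired vectors must have equal length")
    if a.size < 3:
        raise SrsCatError("bland_altman requires at least 3 pairs")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lower, upper = mean - 2.0 * sd, mean + 2.0 * sd
    if sd == 0.0:  # all differences identical: perfect agreement with the mean
        within = 100.0
    else:
        within = float(100.0 * np.mean((diff > lower) & (diff < upper)))
    return BlandAltmanResult(mean, sd, (lower, upper), within, int(a.size))


def descriptive_table(
    table: pd.DataFrame, group_by, value: str = "scaled_score"
) -> pd.DataFrame:
    """Per-group n, median, IQR, mean, SD of ``value``.

    Cells with exactly one respondent are suppressed: their statistics are
    withheld (NaN) and flagged in the ``suppressed`` column.
    """
    group_by = [group_by] if isinstance(group_by, str) else list(group_by)
    for col in group_by + [value]:
        if col not in table.columns:
            raise SrsCatError(f"column {col!r} not in score table")

    def summarize(vals: pd.Series) -> pd.Series:
        vals = vals.dropna()
        n = len(vals)
        if n == 1:
            return pd.Series(
                {"n": 1, "median": np.nan, "iqr": np.nan, "mean": np.nan,
                 "sd": np.nan, "suppressed": True}
            )
        q1, q3 = (vals.quantile([0.25, 0.75]) if n else (np.nan, np.nan))
        return pd.Series(
            {
                "n": n,
                "median": vals.median(),
                "iqr": q3 - q1,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if n > 1 else np.nan,
                "suppressed": False,
            }
        )

    out = table.groupby(group_by, dropna=False, observed=True)[value].apply(summarize)
    out = out.unstack(-1).reset_index()
    out["n"] = out["n"].astype(int)
    out["suppressed"] = out["suppressed"].astype(bool)
    return out


def density_shift_summary(
    table: pd.DataFrame,
    reference_arm: str,
    comparison_arm: str,
    group_by=None,
    value: str = "scaled_score",
    arm_col: str = "arm",
) -> pd.DataFrame:
    """Mean shift of the comparison arm relative to the reference arm in
    pooled-SD units, with the equal-variance normal overlap coefficient
    2 * Phi(-|shift| / 2) of the two approximating densities."""
    groups = (
        [(None, table)]
        if group_by is None
        else list(table.groupby(group_by, dropna=False, observed=True))
    )
    rows = []
    for key, sub in groups:
        ref = sub.loc[sub[arm_col] == reference_arm, value].dropna().to_numpy()
        cmp_ = sub.loc[sub[arm_col] == comparison_arm, value].dropna().to_numpy()
        if ref.size < 2 or cmp_.size < 2:
            warnings.warn(
                f"group {key!r}: fewer than 2 observations per arm; skipped",
                stacklevel=2,
            )
            continue
        try:
            shift = cohens_d(cmp_, ref)
        except UndefinedEffectError:
            shift = 0.0 if np.mean(cmp_) == np.mean(ref) else np.inf
        overlap = float(2.0 * norm.cdf(-abs(shift) / 2.0)) if np.isfinite(shift) else 0.0
        rows.append(
            {
                "group": key,
                "reference_arm": reference_arm,
                "comparison_arm": comparison_arm,
                "shift_sd": shift,
                "overlap": overlap,
                "n_reference": ref.size,
                "n_comparison": cmp_.size,
            }
        )
    return pd.DataFrame(rows)
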