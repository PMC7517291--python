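"""Cohort-level biomarker evaluation: group comparison, ROC, Youden point.

The positive class throughout is "relapsing to AF".  Each predictor is
tested for normality per group (Kolmogorov-Smirnov against the standard
normal, on standardized data, alpha = 0.05); when both groups pass, a
two-sample Student's t-test compares them, otherwise a Wilcoxon rank-sum
test.  Discriminant ability is the area under the ROC curve (AROC),
computed as the probability that a positive outranks a negative with ties
counting one half, and the operating point maximizes Youden's statistic
Se + Sp over thresholds placed at midpoints between consecutive sorted
unique scores (plus the two infinite endpoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "GroupedScores",
    "ComparisonResult",
    "RocResult",
    "compare_groups",
    "roc_analysis",
    "evaluate_cohort",
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
]

POSITIVE_LABEL = "AF-relapse"
NEGATIVE_LABEL = "SR"


@dataclass
class GroupedScores:
    """Predictor values split by outcome group.

    ``higher_is_positive`` records the direction in which the predictor
    indicates relapse (False e.g. for the normalized f-wave amplitude,
    which is lower in relapsing patients).
    """

    scores_positive: np.ndarray
    scores_negative: np.ndarray
    predictor_name: str = ""
    higher_is_positive: bool = True

    def __post_init__(self) -> None:
        self.scores_positive = np.asarray(self.scores_positive, dtype=np.float64)
        self.scores_negative = np.asarray(self.scores_negative, dtype=np.float64)
        if self.scores_positive.size == 0 or self.scores_negative.size == 0:
            raise ValueError("both groups must be non-empty")
        if not (
            np.all(np.isfinite(self.scores_positive))
            and np.all(np.isfinite(self.scores_negative))
        ):
            raise ValueError("scores must be finite")


@dataclass
class ComparisonResult:
    p_value: float
    test_used: str  # "t-test" | "wilcoxon"
    normal_positive: bool
    normal_negative: bool
    median_positive: float
    median_negative: float
    iqr_positive: float
    iqr_negative: float


@dataclass
class RocResult:
    auroc: float
    threshold: float
    se: float
    sp: float
    direction: str  # ">=" | "<="
    degenerate: bool = False


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    sd = np.std(x, ddof=1)
    if sd <= 0:
        return False
    z = (x - np.mean(x)) / sd
    return sstats.kstest(z, "norm").pvalue >= alpha


def compare_groups(scores: GroupedScores, alpha: float = 0.05) -> ComparisonResult:
    """Normality-routed two-group comparison.

    Needs at least 3 values per group.  A zero-variance group skips the
    normality test and routes to the rank-sum test with a warning.
    Medians and interquartile ranges are always reported.
    """
    pos, neg = scores.scores_positive, scores.scores_negative
    if pos.size < 3 or neg.size < 3:
        raise ValueError("need at least 3 values per group")
    zero_var = np.std(pos, ddof=1) <= 0 or np.std(neg, ddof=1) <= 0
    if zero_var:
        warnings.warn(
            "zero variance in a group; using the rank-sum test",
            RuntimeWarning,
            stacklevel=2,
        )
        normal_pos = normal_neg = False
    else:
        normal_pos = _is_normal(pos, alpha)
        normal_neg = _is_normal(neg, alpha)
    if normal_pos and normal_neg:
        test_used = "t-test"
        p = float(sstats.ttest_ind(pos, neg).pvalue)
    else:
        test_used = "wilcoxon"
        p = float(sstats.ranksums(pos, neg).pvalue)
    q75p, q25p = np.percentile(pos, [75, 25])
    q75n, q25n = np.percentile(neg, [75, 25])
    return ComparisonResult(
        p_value=p,
        test_used=test_used,
        normal_positive=normal_pos,
        normal_negative=normal_neg,
        median_positive=float(np.median(pos)),
        median_negative=float(np.median(neg)),
        iqr_positive=float(q75p - q25p),
        iqr_negative=float(q75n - q25n),
    )


def _auroc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Probability a positive outranks a negative, ties counting 1/2."""
    combined = np.concatenate([pos, neg])
    ranks = sstats.rankdata(combined)
    r_pos = ranks[: pos.size].sum()
    n_pos, n_neg = pos.size, neg.size
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_analysis(scores: GroupedScores) -> RocResult:
    """AROC and the Youden-optimal operating point.

    Orientation follows ``higher_is_positive`` (the AROC >= 0.5 convention
    is not forced).  Thresholds are midpoints between consecutive sorted
    unique scores plus the infinite endpoints; on ties of Se + Sp, the
    threshold with the higher specificity wins.  Identical constant scores
    in both groups give AROC = 0.5 with the degenerate flag set.
    """
    pos = scores.scores_positive
    neg = scores.scores_negative
    sign = 1.0 if scores.higher_is_positive else -1.0
    p, q = sign * pos, sign * neg

    degenerate = (
        np.ptp(np.concatenate([p, q])) == 0.0
    )
    auroc = 0.5 if degenerate else _auroc_rank(p, q)

    uniq = np.unique(np.concatenate([p, q]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    best = (-1.0, -1.0, np.inf)  # (youden, sp, thr)
    best_se = best_sp = 0.0
    for thr in thresholds:
        se = float(np.mean(p >= thr))
        sp = float(np.mean(q < thr))
        youden = se + sp
        if youden > best[0] + 1e-12 or (
            abs(youden - best[0]) <= 1e-12 and sp > best[1] + 1e-12
        ):
            best = (youden, sp, thr)
            best_se, best_sp = se, sp
    thr = best[2]
    direction = ">=" if scores.higher_is_positive else "<="
    threshold = thr if scores.higher_is_positive else -thr
    return RocResult(
        auroc=auroc,
        threshold=float(threshold),
        se=best_se,
        sp=best_sp,
        direction=direction,
        degenerate=bool(degenerate),
    )


# predictors whose value decreases in relapsing patients
_LOWER_IS_POSITIVE = ("nFWA",)


def default_orientation(predictor: str) -> bool:
    return not any(predictor.endswith(name) or predictor == name for name in _LOWER_IS_POSITIVE)


def evaluate_cohort(
    feature_table: pd.DataFrame,
    group_col: str = "group",
    predictors: Optional[List[str]] = None,
    orientation: Optional[Dict[str, bool]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-predictor comparison and ROC analysis over a labeled cohort.

    ``feature_table`` holds one row per record with a group label column
    ("AF-relapse" positive, "SR" negative) and numeric predictor columns.
    Records with a missing value for a predictor are excluded pairwise
    (count logged in the ``n_pos``/``n_neg`` columns).  Returns one row
    per predictor with medians (IQRs), p-value, test, AROC, Se, Sp and
    threshold.
    """
    if group_col not in feature_table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    if predictors is None:
        predictors = [
            c
            for c in feature_table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(feature_table[c])
        ]
    orientation = orientation or {}
    rows = []
    for name in predictors:
        sub = feature_table[[group_col, name]].dropna()
        pos = sub.loc[sub[group_col] == POSITIVE_LABEL, name].to_numpy(float)
        neg = sub.loc[sub[group_col] == NEGATIVE_LABEL, name].to_numpy(float)
        if pos.size < 3 or neg.size < 3:
            continue
        hip = orientation.get(name, default_orientation(name))
        scores = GroupedScores(pos, neg, predictor_name=name, higher_is_positive=hip)
        comp = compare_groups(scores, alpha=alpha)
        roc = roc_analysis(scores)
        rows.append(
            {
                "predictor": name,
                "median_pos": comp.median_positive,
                "iqr_pos": comp.iqr_positive,
                "median_neg": comp.median_negative,
                "iqr_neg": comp.iqr_negative,
                "p_value": comp.p_value,
                "test": comp.test_used,
                "AROC": roc.auroc,
                "Se": roc.se,
                "Sp": roc.sp,
                "threshold": roc.threshold,
                "direction": roc.direction,
                "n_pos": pos.size,
                "n_neg": neg.size,
            }
        )
    return pd.DataFrame(rows)
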