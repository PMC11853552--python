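"""ROC analysis, Youden thresholding and subtype performance tables.

The composite risk score is a small integer, so ties are pervasive and are
handled explicitly throughout: the AUC is the Mann-Whitney concordance
probability with tied pairs counted 1/2, ROC thresholds are the distinct
observed values, and Youden's J is maximised over those observed values
with deterministic tie-breaks. A ``direction`` of ``"le"`` (low scores flag
the target, as for the non-obstructive subtypes) negates the score
internally, so reported AUCs exceed 0.5 whenever the low-score rule
discriminates.

The 95% AUC confidence interval uses DeLong's asymptotic variance of the
Mann-Whitney statistic (computed from midrank structural components); a
Hanley-McNeil interval is available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortSplit
from .errors import InputError, UndefinedMetricError
from .schema import LABEL_COLUMN
from .scorecard import ScoreCard, score_cohort

Direction = Literal["ge", "le"]

#: Table of one-vs-rest targets and their risk-score direction: high scores
#: flag prostatic obstruction, low scores flag the non-obstructive subtypes.
#: "HSB_NORMAL" pools the hypersensitive and stable (normal) bladders.
DEFAULT_SUBTYPE_SPEC: dict[str, Direction] = {
    "BPO": "ge",
    "BND": "le",
    "PRES": "le",
    "DV": "le",
    "DU": "le",
    "HSB_NORMAL": "le",
}

#: Label sets behind composite targets.
POOLED_TARGETS: dict[str, frozenset[str]] = {
    "HSB_NORMAL": frozenset({"HSB", "STABLE"}),
}


@dataclass
class DiagnosticPerformance:
    """One target diagnosis on one data split at one threshold."""

    target_label: str
    split: str
    threshold: float
    direction: Direction
    sensitivity: float
    specificity: float
    auc: float = math.nan
    auc_ci: tuple[float, float] = (math.nan, math.nan)
    error: str | None = None


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered from (0,0) to (1,1), one per distinct threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise InputError("ROC curve must start at (0,0) and end at (1,1)")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise InputError("ROC coordinates must be non-decreasing")


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    y = y.astype(float)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(s)):
        raise InputError("scores contain non-finite values")
    if not np.all((y == 0) | (y == 1)):
        raise InputError("labels must be binary (0/1)")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise UndefinedMetricError("both classes must be present")
    return s, y.astype(int)


def _oriented(scores: np.ndarray, direction: Direction) -> np.ndarray:
    if direction == "ge":
        return scores
    if direction == "le":
        return -scores
    raise InputError(f"direction must be 'ge' or 'le', got {direction!r}")


def roc_curve(scores, labels, direction: Direction = "ge") -> RocCurve:
    """Empirical ROC curve with one point per distinct threshold.

    For ``direction="le"`` the score is negated internally; the reported
    thresholds are on the original scale.
    """
    s, y = _as_arrays(scores, labels)
    o = _oriented(s, direction)
    order = np.argsort(-o, kind="stable")
    o_sorted, y_sorted = o[order], y[order]
    distinct = np.flatnonzero(np.diff(o_sorted) != 0)
    last = np.concatenate([distinct, [len(o_sorted) - 1]])
    tps = np.cumsum(y_sorted)[last]
    fps = np.cumsum(1 - y_sorted)[last]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thr_internal = np.concatenate([[np.inf], o_sorted[last]])
    thresholds = thr_internal if direction == "ge" else -thr_internal
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(scores, labels, direction: Direction = "ge") -> float:
    """Mann-Whitney concordance probability: P(score_pos > score_neg) +
    P(tie)/2, with ``"le"`` scores negated first."""
    s, y = _as_arrays(scores, labels)
    o = _oriented(s, direction)
    pos, neg = o[y == 1], o[y == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m, n = len(pos), len(neg)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via midrank structural components."""
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    a = float((all_r[:m].sum() - m * (m + 1) / 2) / (m * n))
    v01 = (all_r[:m] - pos_r) / n          # per-positive placement values
    v10 = 1.0 - (all_r[m:] - neg_r) / m    # per-negative placement values
    var = 0.0
    if m > 1:
        var += float(np.var(v01, ddof=1)) / m
    if n > 1:
        var += float(np.var(v10, ddof=1)) / n
    return a, var


def auc_ci_delong(
    scores,
    labels,
    direction: Direction = "ge",
    level: float = 0.95,
    method: Literal["delong", "hanley-mcneil"] = "delong",
) -> tuple[float, float]:
    """Asymptotic ``level`` confidence interval for the AUC, clipped to
    [0, 1]. Perfect separation gives zero estimated variance; the degenerate
    point interval is returned with a warning."""
    s, y = _as_arrays(scores, labels)
    o = _oriented(s, direction)
    pos, neg = o[y == 1], o[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise UndefinedMetricError("need at least 2 observations per class for a CI")
    a, var = _delong_variance(pos, neg)
    if method == "hanley-mcneil":
        m, n = len(pos), len(neg)
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)
    elif method != "delong":
        raise InputError(f"unknown CI method {method!r}")
    if var <= 0:
        warnings.warn(
            "degenerate AUC variance (perfect separation); returning point interval",
            stacklevel=2,
        )
        return (a, a)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return (max(0.0, a - half), min(1.0, a + half))


def youden_optimal_threshold(scores, labels, direction: Direction = "ge") -> float:
    """Observed score value maximising Youden's J = sensitivity +
    specificity - 1. Ties break toward higher sensitivity, then toward the
    smaller threshold on the original score scale."""
    s, y = _as_arrays(scores, labels)
    o = _oriented(s, direction)
    pos, neg = np.sort(o[y == 1]), np.sort(o[y == 0])
    cands = np.unique(o)
    # "positive" means oriented score >= candidate, which on the original
    # scale is score >= t for "ge" and score <= t for "le"
    sens = 1.0 - np.searchsorted(pos, cands, side="left") / len(pos)
    spec = np.searchsorted(neg, cands, side="left") / len(neg)
    j = sens + spec - 1.0
    idx = np.flatnonzero(j >= j.max() - 1e-12)
    idx = idx[sens[idx] >= sens[idx].max() - 1e-12]
    if direction == "ge":
        return float(cands[idx].min())
    return float(-cands[idx].max())


def confusion_metrics(
    scores, labels, threshold: float, direction: Direction = "ge",
    target_label: str = "", split: str = "",
) -> DiagnosticPerformance:
    """Sensitivity/specificity at a fixed threshold; "positive prediction"
    means score >= threshold for ``"ge"`` and score <= threshold for
    ``"le"``."""
    s, y = _as_arrays(scores, labels)
    if direction == "ge":
        pred = s >= threshold
    elif direction == "le":
        pred = s <= threshold
    else:
        raise InputError(f"direction must be 'ge' or 'le', got {direction!r}")
    pos, neg = y == 1, y == 0
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[neg]))
    return DiagnosticPerformance(
        target_label=target_label,
        split=split,
        threshold=float(threshold),
        direction=direction,
        sensitivity=sens,
        specificity=spec,
    )


def target_members(target: str) -> frozenset[str]:
    return POOLED_TARGETS.get(target, frozenset({target}))


def evaluate_all_subtypes(
    split: CohortSplit,
    cohort: pd.DataFrame,
    card: ScoreCard,
    subtype_spec: Mapping[str, Direction] | None = None,
) -> pd.DataFrame:
    """One-vs-rest performance of the composite risk score for each target
    subtype, on the training and validation splits.

    The Youden-optimal threshold is chosen on the training split only and
    frozen for validation. Targets absent from a split (or present in all
    its rows) yield a flagged row with NaN metrics; the other rows are still
    produced. Returns a tidy DataFrame with columns target, split,
    threshold, direction, sensitivity, specificity, auc, ci_low, ci_high,
    error.
    """
    spec = dict(subtype_spec) if subtype_spec is not None else dict(DEFAULT_SUBTYPE_SPEC)
    scores = score_cohort(cohort, card).to_numpy()
    labels = cohort[LABEL_COLUMN].to_numpy()
    parts = {
        "training": split.training_indices,
        "validation": split.validation_indices,
    }
    rows = []
    for target, direction in spec.items():
        members = target_members(target)
        y_all = np.isin(labels, list(members)).astype(int)
        tr = parts["training"]
        try:
            threshold = youden_optimal_threshold(scores[tr], y_all[tr], direction)
        except UndefinedMetricError as exc:
            for part in parts:
                rows.append(_error_row(target, part, direction, str(exc)))
            continue
        for part, idx in parts.items():
            try:
                perf = confusion_metrics(
                    scores[idx], y_all[idx], threshold, direction,
                    target_label=target, split=part,
                )
                perf.auc = auc(scores[idx], y_all[idx], direction)
                try:
                    perf.auc_ci = auc_ci_delong(scores[idx], y_all[idx], direction)
                except UndefinedMetricError:
                    perf.auc_ci = (math.nan, math.nan)
                rows.append(_perf_row(perf))
            except UndefinedMetricError as exc:
                rows.append(_error_row(target, part, direction, str(exc), threshold))
    return pd.DataFrame(
        rows,
        columns=[
            "target", "split", "threshold", "direction",
            "sensitivity", "specificity", "auc", "ci_low", "ci_high", "error",
        ],
    )


def _perf_row(p: DiagnosticPerformance) -> dict:
    return {
        "target": p.target_label,
        "split": p.split,
        "threshold": p.threshold,
        "direction": p.direction,
        "sensitivity": p.sensitivity,
        "specificity": p.specificity,
        "auc": p.auc,
        "ci_low": p.auc_ci[0],
        "ci_high": p.auc_ci[1],
        "error": None,
    }


def _error_row(
    target: str, part: str, direction: Direction, message: str,
    threshold: float = math.nan,
) -> dict:
    return {
        "target": target,
        "split": part,
        "threshold": threshold,
        "direction": direction,
        "sensitivity": math.nan,
        "specificity": math.nan,
        "auc": math.nan,
        "ci_low": math.nan,
        "ci_high": math.nan,
        "error": message,
    }
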