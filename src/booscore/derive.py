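"""Score-card derivation from a labelled cohort.

The published card fixed each variable's cutoffs "with regard to the
specificity of predicting BOO"; this module makes that principle an
algorithm. For each variable the candidate cutoffs are the midpoints of
consecutive sorted unique observed values (plus the two infinities, which
can never be selected); for an ascending grid of target specificities the
k-th cutoff is the least extreme candidate (smallest for direction ">=",
largest for "<=") whose specificity against the BOO label first reaches the
k-th target — deterministic, and equivalent to maximizing sensitivity among
the qualifying candidates, since sensitivity is anti-monotone in the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DerivationError, InputError, UndefinedMetricError
from .schema import BOO_LABELS, LABEL_COLUMN
from .scorecard import Bin, ScoreCard, VariableRule

Direction = Literal["ge", "le"]
_INF = math.inf


@dataclass(frozen=True)
class CutoffPerformance:
    """Sensitivity/specificity of one binary split of a cohort."""

    variable: str
    cutoff: float
    direction: Direction
    sensitivity: float
    specificity: float


def _pos_neg_values(
    cohort: pd.DataFrame, variable: str, positive_labels: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    if variable not in cohort.columns:
        raise InputError(f"cohort has no column {variable!r}")
    if LABEL_COLUMN not in cohort.columns:
        raise InputError(f"cohort has no column {LABEL_COLUMN!r}")
    values = cohort[variable].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise InputError(f"column {variable!r} contains non-finite values")
    is_pos = cohort[LABEL_COLUMN].isin(set(positive_labels)).to_numpy()
    pos, neg = values[is_pos], values[~is_pos]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError(
            "sensitivity/specificity undefined: cohort must contain both "
            "positive- and negative-label rows"
        )
    return pos, neg


def variable_sens_spec(
    cohort: pd.DataFrame,
    variable: str,
    cutoff: float,
    direction: Direction,
    positive_labels: Iterable[str] = BOO_LABELS,
) -> CutoffPerformance:
    """Sensitivity and specificity of flagging ``variable`` ``>=``/``<=``
    ``cutoff`` as a prediction of the positive labels (default: BOO)."""
    pos, neg = _pos_neg_values(cohort, variable, positive_labels)
    if direction == "ge":
        sens = float(np.mean(pos >= cutoff))
        spec = float(np.mean(neg < cutoff))
    elif direction == "le":
        sens = float(np.mean(pos <= cutoff))
        spec = float(np.mean(neg > cutoff))
    else:
        raise InputError(f"direction must be 'ge' or 'le', got {direction!r}")
    return CutoffPerformance(variable, float(cutoff), direction, sens, spec)


def candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive sorted unique values, plus the infinities."""
    u = np.unique(np.asarray(values, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[-_INF], mids, [_INF]])


def derive_variable_rule(
    cohort: pd.DataFrame,
    variable: str,
    max_points: int,
    specificity_grid: Sequence[float],
    direction: Direction,
    positive_labels: Iterable[str] = BOO_LABELS,
) -> VariableRule:
    """Derive an ordinal binning rule for one variable.

    ``specificity_grid`` must be strictly increasing with one entry per
    point level above zero (``len == max_points``). Raises
    :class:`DerivationError` if any target is unreachable with a finite
    cutoff or if two targets collapse onto the same cutoff.
    """
    if max_points not in (1, 2, 3):
        raise InputError(f"max_points must be 1, 2 or 3, got {max_points}")
    grid = [float(t) for t in specificity_grid]
    if len(grid) != max_points or any(b <= a for a, b in zip(grid, grid[1:])):
        raise InputError(
            "specificity_grid must be strictly increasing with one target "
            f"per point level ({max_points}), got {specificity_grid!r}"
        )
    pos, neg = _pos_neg_values(cohort, variable, positive_labels)
    if len(np.unique(np.concatenate([pos, neg]))) < 2:
        raise DerivationError(
            f"{variable!r} is degenerate (constant); no informative cutoff exists"
        )
    cands = candidate_cutoffs(np.concatenate([pos, neg]))
    # vectorised sens/spec at every candidate
    pos_s, neg_s = np.sort(pos), np.sort(neg)
    if direction == "ge":
        sens = 1.0 - np.searchsorted(pos_s, cands, side="left") / len(pos)
        spec = np.searchsorted(neg_s, cands, side="left") / len(neg)
    elif direction == "le":
        sens = np.searchsorted(pos_s, cands, side="right") / len(pos)
        spec = 1.0 - np.searchsorted(neg_s, cands, side="right") / len(neg)
    else:
        raise InputError(f"direction must be 'ge' or 'le', got {direction!r}")

    cutoffs: list[float] = []
    for target in grid:
        usable = (spec >= target - 1e-12) & np.isfinite(cands)
        if not usable.any():
            raise DerivationError(
                f"{variable!r}: no finite cutoff reaches specificity target {target}"
            )
        idx = np.flatnonzero(usable)
        # first attainment: the least extreme cutoff reaching the target.
        # Specificity is monotone in the cutoff, sensitivity anti-monotone,
        # so this simultaneously maximizes sensitivity among qualifying cuts.
        cut = cands[idx].min() if direction == "ge" else cands[idx].max()
        cutoffs.append(float(cut))

    ordered = cutoffs if direction == "ge" else cutoffs[::-1]
    if any(b <= a for a, b in zip(ordered, ordered[1:])):
        raise DerivationError(
            f"{variable!r}: specificity targets {grid} collapse onto "
            f"non-distinct cutoffs {cutoffs}"
        )

    bins: list[Bin] = []
    if direction == "ge":
        edges = [-_INF] + cutoffs + [_INF]
        for k in range(len(edges) - 1):
            bins.append(
                Bin(
                    lower=edges[k],
                    upper=edges[k + 1],
                    lower_closed=k > 0,
                    upper_closed=False,
                    points=k,
                )
            )
    else:
        edges = [-_INF] + cutoffs[::-1] + [_INF]
        pts = list(range(len(cutoffs), -1, -1))
        for k in range(len(edges) - 1):
            bins.append(
                Bin(
                    lower=edges[k],
                    upper=edges[k + 1],
                    lower_closed=False,
                    upper_closed=k < len(edges) - 2,
                    points=pts[k],
                )
            )
    note = "higher values are higher risk" if direction == "ge" else "lower values are higher risk"
    return VariableRule(variable=variable, bins=tuple(bins), direction_note=note)


def welch_screen(
    cohort: pd.DataFrame,
    variables: Iterable[str],
    positive_labels: Iterable[str] = BOO_LABELS,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Welch two-sample t-test p-value per variable (positive vs negative
    group); used to pre-filter score-card variables at ``alpha``."""
    out = {}
    for v in variables:
        pos, neg = _pos_neg_values(cohort, v, positive_labels)
        if np.ptp(pos) == 0 and np.ptp(neg) == 0:
            out[v] = 1.0 if pos.mean() == neg.mean() else 0.0
            continue
        out[v] = float(stats.ttest_ind(pos, neg, equal_var=False).pvalue)
    return out


def build_score_card(
    cohort: pd.DataFrame,
    spec: Mapping[str, tuple[int, Sequence[float], Direction]],
    positive_labels: Iterable[str] = BOO_LABELS,
    screen: bool = False,
    alpha: float = 0.05,
    name: str = "derived",
) -> ScoreCard:
    """Assemble a :class:`ScoreCard` by deriving one rule per variable in
    ``spec`` (mapping variable -> (max_points, specificity_grid, direction)).

    With ``screen=True`` variables whose Welch p-value against the positive
    grouping is >= ``alpha`` are dropped before derivation, mirroring
    selection of significantly different variables.
    """
    variables = list(spec)
    missing = [v for v in variables if v not in cohort.columns]
    if missing:
        raise InputError(f"cohort missing variables: {missing}")
    if screen and variables:
        pvals = welch_screen(cohort, variables, positive_labels, alpha)
        variables = [v for v in variables if pvals[v] < alpha]
    rules = []
    for v in variables:
        max_points, grid, direction = spec[v]
        try:
            rules.append(
                derive_variable_rule(cohort, v, max_points, grid, direction, positive_labels)
            )
        except DerivationError as exc:
            raise DerivationError(f"while deriving rule for {v!r}: {exc}") from exc
    return ScoreCard(rules=tuple(rules), name=name)
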