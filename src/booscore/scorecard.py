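"""The point-based BOO risk score card.

A score card is an ordered set of per-variable binning rules. Each rule
partitions its variable's domain into contiguous intervals carrying integer
point values (0 up to 3); a patient's risk score is the sum of the points
over all rules. The published card spans eight office-based variables —
age, IPSS voiding/storage ratio, Qmax, voided volume, total prostate volume,
transition-zone index, intravesical prostatic protrusion and the prostatic
urethrovesical angle — with a maximum attainable score of 18.

Cards are data, not code: the default card ships as a packaged JSON config
(``data/default_card.json``) and user cards load from the same format, so
alternative cards (e.g. the seven-variable variant without age) need no code
change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

_INF = math.inf


@dataclass(frozen=True)
class Bin:
    """One interval of a variable's domain and the points it carries.

    ``lower``/``upper`` may be ``-inf``/``inf``; closedness flags state
    whether each finite endpoint belongs to the interval.
    """

    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    points: int

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.lower_closed and value == self.lower)
        below = value < self.upper or (self.upper_closed and value == self.upper)
        return above and below

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigError(f"bin lower {self.lower} must be < upper {self.upper}")
        if self.points < 0 or int(self.points) != self.points:
            raise ConfigError(f"bin points must be a non-negative integer, got {self.points}")


@dataclass(frozen=True)
class VariableRule:
    """Ordered bins for one scored variable.

    Bins must be listed in ascending value order, pairwise contiguous
    (each bin's upper endpoint is the next bin's lower endpoint, with
    complementary closedness) so that every value of the covered domain
    falls in exactly one bin.
    """

    variable: str
    bins: tuple[Bin, ...]
    direction_note: str = ""

    def __post_init__(self) -> None:
        if not self.bins:
            raise ConfigError(f"rule for {self.variable!r} has no bins")
        for a, b in zip(self.bins, self.bins[1:]):
            if a.upper != b.lower or a.upper_closed == b.lower_closed:
                raise ConfigError(
                    f"rule for {self.variable!r}: bins must be contiguous and "
                    f"non-overlapping at {a.upper}"
                )

    @property
    def domain(self) -> tuple[float, float]:
        return self.bins[0].lower, self.bins[-1].upper

    @property
    def max_points(self) -> int:
        return max(b.points for b in self.bins)


@dataclass(frozen=True)
class ScoreCard:
    """An ordered collection of :class:`VariableRule`, one per scored variable."""

    rules: tuple[VariableRule, ...] = field(default_factory=tuple)
    name: str = ""

    def __post_init__(self) -> None:
        names = [r.variable for r in self.rules]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate variable in score card: {names}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(r.variable for r in self.rules)

    def rule(self, variable: str) -> VariableRule:
        for r in self.rules:
            if r.variable == variable:
                return r
        raise InputError(f"score card has no rule for {variable!r}")


def assign_points(value: float, rule: VariableRule) -> int:
    """Points for ``value`` under ``rule``.

    Raises :class:`InputError` for non-finite values or values outside the
    rule's domain — a value is never silently scored 0.
    """
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise InputError(f"{rule.variable}: non-numeric value {value!r}") from None
    if not math.isfinite(value):
        raise InputError(f"{rule.variable}: non-finite value {value!r}")
    for b in rule.bins:
        if b.contains(value):
            return b.points
    lo, hi = rule.domain
    raise InputError(f"{rule.variable}={value} outside rule domain [{lo}, {hi}]")


def compute_risk_score(patient: Mapping[str, float] | pd.Series, card: ScoreCard) -> int:
    """Composite risk score for one patient: sum of per-rule points."""
    total = 0
    for r in card.rules:
        if r.variable not in patient:
            raise InputError(f"patient record missing scored field {r.variable!r}")
        v = patient[r.variable]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise InputError(f"patient record missing scored field {r.variable!r}")
        total += assign_points(v, r)
    return total


def _rule_points_vector(values: np.ndarray, rule: VariableRule) -> np.ndarray:
    """Vectorised point lookup; semantics identical to :func:`assign_points`."""
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise InputError(f"{rule.variable}: non-finite value at row {bad}")
    conds = []
    for b in rule.bins:
        above = values >= b.lower if b.lower_closed else values > b.lower
        below = values <= b.upper if b.upper_closed else values < b.upper
        conds.append(above & below)
    pts = np.select(conds, [b.points for b in rule.bins], default=-1)
    if np.any(pts < 0):
        bad = int(np.flatnonzero(pts < 0)[0])
        lo, hi = rule.domain
        raise InputError(
            f"{rule.variable}={values[bad]} at row {bad} outside rule domain [{lo}, {hi}]"
        )
    return pts


def score_cohort(cohort: pd.DataFrame, card: ScoreCard) -> pd.Series:
    """Integer risk score per cohort row (vectorised; bit-identical to the
    row-wise :func:`compute_risk_score` path)."""
    missing = [r.variable for r in card.rules if r.variable not in cohort.columns]
    if missing:
        raise InputError(f"cohort missing scored columns: {missing}")
    total = np.zeros(len(cohort), dtype=np.int64)
    for r in card.rules:
        total += _rule_points_vector(cohort[r.variable].to_numpy(dtype=float), r)
    return pd.Series(total, index=cohort.index, name="boo_risk_score")


def max_score(card: ScoreCard) -> int:
    """Largest attainable composite score: sum of each rule's maximum points."""
    return sum(r.max_points for r in card.rules)


# ---------------------------------------------------------------------------
# Serialization (JSON card config)

def _bin_to_dict(b: Bin) -> dict:
    return {
        "lower": None if b.lower == -_INF else b.lower,
        "upper": None if b.upper == _INF else b.upper,
        "lower_closed": b.lower_closed,
        "upper_closed": b.upper_closed,
        "points": b.points,
    }


def _bin_from_dict(d: Mapping) -> Bin:
    return Bin(
        lower=-_INF if d["lower"] is None else float(d["lower"]),
        upper=_INF if d["upper"] is None else float(d["upper"]),
        lower_closed=bool(d["lower_closed"]),
        upper_closed=bool(d["upper_closed"]),
        points=int(d["points"]),
    )


def card_to_dict(card: ScoreCard) -> dict:
    return {
        "name": card.name,
        "rules": [
            {
                "variable": r.variable,
                "direction_note": r.direction_note,
                "bins": [_bin_to_dict(b) for b in r.bins],
            }
            for r in card.rules
        ],
    }


def card_from_dict(d: Mapping) -> ScoreCard:
    try:
        rules = tuple(
            VariableRule(
                variable=r["variable"],
                direction_note=r.get("direction_note", ""),
                bins=tuple(_bin_from_dict(b) for b in r["bins"]),
            )
            for r in d["rules"]
        )
        return ScoreCard(rules=rules, name=d.get("name", ""))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed score-card config: {exc}") from exc


def save_score_card(card: ScoreCard, path: str | Path) -> None:
    Path(path).write_text(json.dumps(card_to_dict(card), indent=2) + "\n")


def load_score_card(path: str | Path) -> ScoreCard:
    try:
        d = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read score card {path}: {exc}") from exc
    return card_from_dict(d)


def packaged_card(name: str = "default") -> ScoreCard:
    """Load a card shipped with the package: ``"default"`` (eight variables)
    or ``"no_age"`` (the seven-variable variant without the age row)."""
    fname = {"default": "default_card.json", "no_age": "no_age_card.json"}.get(name)
    if fname is None:
        raise InputError(f"unknown packaged card {name!r}")
    text = resources.files("booscore.data").joinpath(fname).read_text()
    return card_from_dict(json.loads(text))


def default_score_card() -> ScoreCard:
    """The published eight-variable card (maximum composite score 18)."""
    return packaged_card("default")
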