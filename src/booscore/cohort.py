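"""Synthetic LUTS cohort generator and training/validation splitter.

The generator emulates a cohort of men with medication-refractory lower
urinary tract symptoms, each carrying eleven office-based clinical variables
and a videourodynamics-derived LUTD label. Labels are multinomial with the
study prevalences; conditional on the obstruction group (BOO = BND + BPO vs
non-BOO) the continuous variables follow a Gaussian copula with
group-specific marginal means/SDs, truncated to physiological bounds by
rejection.

Within the BOO group, BPO receives configurable additive mean offsets on the
prostate variables (TPV, TZI, IPP, PUV angle) relative to BND. Offsets are
centred by subtype prevalence and the within-subtype SDs shrunk so the
*pooled* BOO mean and SD stay exactly at the configured group targets; the
offsets therefore add BPO-vs-BND contrast without perturbing the group
marginals they are calibrated against.

RNG contract: one integer seed deterministically spawns three child streams,
in order — (1) label draw, (2) copula draw (incl. rejection redraws),
(3) anything the caller derives (splits take their own seed). Equal seeds
give bit-identical cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .schema import (
    BOO_LABELS,
    CONTINUOUS_VARS,
    COHORT_COLUMNS,
    LABEL_COLUMN,
    LUTD_LABELS,
    group_of,
)

_GROUPS = ("BOO", "non-BOO")

# Subtype prevalences: exact study counts / 355 (they sum to 1; the printed
# one-decimal percentages round from these).
_DEFAULT_COUNTS = {
    "BND": 136, "BPO": 98, "PRES": 26, "DV": 28,
    "STABLE": 9, "DO": 37, "HSB": 7, "DU": 14,
}

# Group-conditional marginal (mean, sd) per variable.
_DEFAULT_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "BOO": {
        "age": (68.6, 8.8),
        "ipss_voiding": (9.1, 5.7),
        "ipss_storage": (8.5, 4.1),
        "ipss_vs": (1.5, 1.7),
        "qmax": (9.4, 5.5),
        "voided_volume": (192.3, 120.5),
        "pvr": (52.4, 89.0),
        "tpv": (40.7, 20.5),
        "tzi": (0.43, 0.15),
        "ipp": (0.4, 0.6),
        "puv_angle": (31.1, 17.9),
    },
    "non-BOO": {
        "age": (66.2, 10.7),
        "ipss_voiding": (10.1, 6.0),
        "ipss_storage": (8.7, 4.0),
        "ipss_vs": (1.6, 1.7),
        "qmax": (12.4, 7.7),
        "voided_volume": (208.4, 128.3),
        "pvr": (36.2, 82.0),
        "tpv": (30.8, 13.4),
        "tzi": (0.35, 0.15),
        "ipp": (0.1, 0.4),
        "puv_angle": (18.6, 17.8),
    },
}

# BPO mean offsets relative to the BOO pool (centred at sampling time);
# roughly half the BOO/non-BOO gap on each prostate variable.
_DEFAULT_SUBTYPE_SHIFTS: dict[str, dict[str, float]] = {
    "BPO": {"tpv": 5.0, "tzi": 0.05, "ipp": 0.25, "puv_angle": 7.0},
}

# Physiologically plausible truncation bounds (rejection sampling).
_DEFAULT_TRUNCATION: dict[str, tuple[float, float]] = {
    "age": (40.0, 95.0),
    "ipss_voiding": (0.0, 20.0),
    "ipss_storage": (0.0, 15.0),
    "ipss_vs": (0.0, 15.0),
    "qmax": (0.0, 60.0),
    "voided_volume": (0.0, 1000.0),
    "pvr": (0.0, 800.0),
    "tpv": (1.0, 150.0),
    "tzi": (0.05, 0.95),
    "ipp": (0.0, 3.0),
    "puv_angle": (0.0, 90.0),
}

# Latent correlation of the Gaussian copula, CONTINUOUS_VARS order. Signs:
# obstruction-related variables co-move (tpv-tzi, tpv-ipp, ipp-puv), flow
# falls with age/prostate size, flow rises with voided volume.
_DEFAULT_CORRELATION_ENTRIES: dict[tuple[str, str], float] = {
    ("age", "qmax"): -0.20,
    ("age", "tpv"): 0.25,
    ("ipss_voiding", "ipss_vs"): 0.45,
    ("ipss_storage", "ipss_vs"): -0.35,
    ("ipss_voiding", "qmax"): -0.25,
    ("qmax", "voided_volume"): 0.45,
    ("qmax", "pvr"): -0.25,
    ("qmax", "tpv"): -0.30,
    ("qmax", "ipp"): -0.25,
    ("tpv", "tzi"): 0.50,
    ("tpv", "ipp"): 0.45,
    ("tpv", "puv_angle"): 0.35,
    ("tzi", "ipp"): 0.30,
    ("ipp", "puv_angle"): 0.40,
}


def default_correlation() -> np.ndarray:
    """The documented default copula correlation matrix."""
    k = len(CONTINUOUS_VARS)
    idx = {v: i for i, v in enumerate(CONTINUOUS_VARS)}
    r = np.eye(k)
    for (a, b), rho in _DEFAULT_CORRELATION_ENTRIES.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
    return r


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (see module docstring)."""

    n: int
    prevalences: dict[str, float]
    group_params: dict[str, dict[str, tuple[float, float]]]
    subtype_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    correlation: np.ndarray = field(default_factory=default_correlation)
    truncation: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_TRUNCATION))
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if set(self.prevalences) != set(LUTD_LABELS):
            raise ConfigError(
                f"prevalences must cover exactly {LUTD_LABELS}, got {sorted(self.prevalences)}"
            )
        probs = np.array([self.prevalences[l] for l in LUTD_LABELS], dtype=float)
        if np.any(probs < 0):
            raise ConfigError("prevalences must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(f"prevalences must sum to 1 (got {probs.sum()!r})")
        for g in _GROUPS:
            params = self.group_params.get(g)
            if params is None or set(params) != set(CONTINUOUS_VARS):
                raise ConfigError(f"group_params[{g!r}] must define all of {CONTINUOUS_VARS}")
            for v, (_, sd) in params.items():
                if sd <= 0:
                    raise ConfigError(f"group_params[{g!r}][{v!r}] sd must be > 0")
        r = np.asarray(self.correlation, dtype=float)
        k = len(CONTINUOUS_VARS)
        if r.shape != (k, k):
            raise ConfigError(f"correlation must be {k}x{k}")
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ConfigError("correlation must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            raise ConfigError("correlation matrix is not positive definite") from None
        for v in CONTINUOUS_VARS:
            lo, hi = self.truncation.get(v, (-math.inf, math.inf))
            if not lo < hi:
                raise ConfigError(f"truncation[{v!r}]: lower {lo} must be < upper {hi}")
        for label in self.subtype_shifts:
            if label not in LUTD_LABELS:
                raise ConfigError(f"subtype_shifts has unknown label {label!r}")
        return self

    def with_wide_bounds(self) -> "GeneratorConfig":
        """Copy of this config with truncation disabled (unbounded marginals);
        used when checking calibration against the raw configured moments."""
        wide = {v: (-math.inf, math.inf) for v in CONTINUOUS_VARS}
        return replace(self, truncation=wide)


def default_generator_config(n: int = 355, seed: int = 0) -> GeneratorConfig:
    """Config reproducing the study's cohort structure: n=355, the eight
    LUTD subtype prevalences, BOO/non-BOO group marginals, the documented
    default copula correlation and physiological truncation bounds."""
    total = sum(_DEFAULT_COUNTS.values())
    prevalences = {l: _DEFAULT_COUNTS[l] / total for l in LUTD_LABELS}
    group_params = {g: dict(p) for g, p in _DEFAULT_GROUP_PARAMS.items()}
    shifts = {l: dict(s) for l, s in _DEFAULT_SUBTYPE_SHIFTS.items()}
    return GeneratorConfig(
        n=n,
        prevalences=prevalences,
        group_params=group_params,
        subtype_shifts=shifts,
        seed=seed,
    )


def _component_params(config: GeneratorConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-subtype (mean, sd) vectors over CONTINUOUS_VARS.

    Shifts are centred within each obstruction group by prevalence weight,
    and the within-subtype SD is reduced so the prevalence-weighted pooled
    variance equals the configured group variance.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in _GROUPS:
        members = [l for l in LUTD_LABELS if group_of(l) == g]
        w = np.array([config.prevalences[l] for l in members], dtype=float)
        if w.sum() <= 0:
            # group absent: parameters unused, take raw values
            w = np.full(len(members), 1.0 / len(members))
        else:
            w = w / w.sum()
        mu_g = np.array([config.group_params[g][v][0] for v in CONTINUOUS_VARS])
        sd_g = np.array([config.group_params[g][v][1] for v in CONTINUOUS_VARS])
        offsets = np.array(
            [
                [config.subtype_shifts.get(l, {}).get(v, 0.0) for v in CONTINUOUS_VARS]
                for l in members
            ]
        )
        centred = offsets - w @ offsets
        shift_var = w @ (centred ** 2)
        comp_var = sd_g ** 2 - shift_var
        bad = comp_var <= 0
        if np.any(bad):
            names = [CONTINUOUS_VARS[i] for i in np.flatnonzero(bad)]
            raise ConfigError(
                f"subtype_shifts too large for group {g!r}: pooled variance of "
                f"{names} would be exceeded by the between-subtype spread"
            )
        comp_sd = np.sqrt(comp_var)
        for i, l in enumerate(members):
            out[l] = (mu_g + centred[i], comp_sd)
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a labelled synthetic cohort of ``config.n`` patients.

    Identical config (including seed) gives a bit-identical DataFrame.
    """
    config.validate()
    if config.n < 1:
        raise InputError(f"cohort size must be >= 1, got {config.n}")
    ss = np.random.SeedSequence(config.seed)
    s_labels, s_values, _s_reserved = ss.spawn(3)
    rng_labels = np.random.default_rng(s_labels)
    rng_values = np.random.default_rng(s_values)

    probs = np.array([config.prevalences[l] for l in LUTD_LABELS])
    labels = rng_labels.choice(len(LUTD_LABELS), size=config.n, p=probs)

    comp = _component_params(config)
    mu = np.empty((config.n, len(CONTINUOUS_VARS)))
    sd = np.empty_like(mu)
    for i, l in enumerate(LUTD_LABELS):
        mask = labels == i
        if mask.any():
            mu[mask] = comp[l][0]
            sd[mask] = comp[l][1]

    chol = np.linalg.cholesky(np.asarray(config.correlation, dtype=float))
    lo = np.array([config.truncation.get(v, (-math.inf, math.inf))[0] for v in CONTINUOUS_VARS])
    hi = np.array([config.truncation.get(v, (-math.inf, math.inf))[1] for v in CONTINUOUS_VARS])

    x = np.empty_like(mu)
    pending = np.arange(config.n)
    for _ in range(1000):
        z = rng_values.standard_normal((len(pending), len(CONTINUOUS_VARS)))
        draw = mu[pending] + sd[pending] * (z @ chol.T)
        ok = np.all((draw >= lo) & (draw <= hi), axis=1)
        x[pending[ok]] = draw[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:
        raise ConfigError(
            "rejection sampling failed to satisfy truncation bounds within "
            "1000 rounds; bounds are likely inconsistent with the marginals"
        )

    df = pd.DataFrame(x, columns=list(CONTINUOUS_VARS))
    df[LABEL_COLUMN] = pd.Series([LUTD_LABELS[i] for i in labels], dtype="object")
    return df[list(COHORT_COLUMNS)]


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint positional index partition into training and validation."""

    training_indices: np.ndarray
    validation_indices: np.ndarray

    def __post_init__(self) -> None:
        tr = set(self.training_indices.tolist())
        va = set(self.validation_indices.tolist())
        if tr & va:
            raise ConfigError("training and validation indices overlap")

    @property
    def n(self) -> int:
        return len(self.training_indices) + len(self.validation_indices)


def split_cohort(
    cohort: pd.DataFrame,
    training_fraction: float,
    seed: int = 0,
    stratify: bool = True,
) -> CohortSplit:
    """Random training/validation partition.

    The training size is ``floor(fraction*n + 0.5)`` (round half up). With
    ``stratify`` (default) the partition preserves each LUTD label's
    proportion within rounding, apportioning per-label training counts by
    largest remainder so the total is exact.
    """
    n = len(cohort)
    if n == 0:
        raise InputError("cannot split an empty cohort")
    if not 0.0 < training_fraction < 1.0:
        raise InputError(f"training_fraction must be in (0, 1), got {training_fraction}")
    n_train = int(math.floor(training_fraction * n + 0.5))
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if stratify and LABEL_COLUMN in cohort.columns:
        labels = cohort[LABEL_COLUMN].to_numpy()
        groups = [np.flatnonzero(labels == l) for l in pd.unique(labels)]
        quotas = np.array([training_fraction * len(g) for g in groups])
        base = np.floor(quotas).astype(int)
        short = n_train - base.sum()
        if short > 0:
            order = np.argsort(-(quotas - base), kind="stable")
            base[order[:short]] += 1
        elif short < 0:
            order = np.argsort(quotas - base, kind="stable")
            for i in order:
                if short == 0:
                    break
                if base[i] > 0:
                    base[i] -= 1
                    short += 1
        train_parts, val_parts = [], []
        for g, k in zip(groups, base):
            perm = rng.permutation(g)
            train_parts.append(perm[:k])
            val_parts.append(perm[k:])
        train = np.sort(np.concatenate(train_parts)).astype(np.int64)
        val = np.sort(np.concatenate(val_parts)).astype(np.int64)
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train]).astype(np.int64)
        val = np.sort(perm[n_train:]).astype(np.int64)
    return CohortSplit(training_indices=train, validation_indices=val)


# ---------------------------------------------------------------------------
# Config serialization (flat JSON)

def config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "n": config.n,
        "seed": config.seed,
        "prevalences": {l: config.prevalences[l] for l in LUTD_LABELS},
        "group_params": {
            g: {v: list(config.group_params[g][v]) for v in CONTINUOUS_VARS}
            for g in _GROUPS
        },
        "subtype_shifts": {l: dict(s) for l, s in config.subtype_shifts.items()},
        "correlation": np.asarray(config.correlation, dtype=float).tolist(),
        "truncation": {
            v: [None if not math.isfinite(b[0]) else b[0],
                None if not math.isfinite(b[1]) else b[1]]
            for v, b in config.truncation.items()
        },
    }


def config_from_dict(d: Mapping) -> GeneratorConfig:
    try:
        trunc = {
            v: (
                -math.inf if b[0] is None else float(b[0]),
                math.inf if b[1] is None else float(b[1]),
            )
            for v, b in d["truncation"].items()
        }
        cfg = GeneratorConfig(
            n=int(d["n"]),
            seed=int(d.get("seed", 0)),
            prevalences={l: float(p) for l, p in d["prevalences"].items()},
            group_params={
                g: {v: (float(m), float(s)) for v, (m, s) in params.items()}
                for g, params in d["group_params"].items()
            },
            subtype_shifts={
                l: {v: float(x) for v, x in s.items()}
                for l, s in d.get("subtype_shifts", {}).items()
            },
            correlation=np.asarray(d["correlation"], dtype=float),
            truncation=trunc,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed generator config: {exc}") from exc
    return cfg.validate()


def save_generator_config(config: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2) + "\n")


def load_generator_config(path: str | Path) -> GeneratorConfig:
    try:
        d = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read generator config {path}: {exc}") from exc
    return config_from_dict(d)
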