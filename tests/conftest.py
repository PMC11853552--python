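import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import booscore as bs

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

#: Finite probe span per scored variable, covering all default-card bins.
PROBE_SPANS = {
    "age": (0.0, 130.0),
    "ipss_vs": (0.0, 12.0),
    "qmax": (0.0, 60.0),
    "voided_volume": (0.0, 650.0),
    "tpv": (0.0, 160.0),
    "tzi": (0.0, 1.0),
    "ipp": (0.0, 3.0),
    "puv_angle": (0.0, 180.0),
}


@pytest.fixture(scope="session")
def default_card():
    return bs.default_score_card()


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized synthetic cohort under the study's default generator."""
    return bs.generate_cohort(bs.default_generator_config(n=2000, seed=2026))


def random_scored_rows(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random in-domain rows over the scored variables."""
    return pd.DataFrame(
        {v: rng.uniform(lo, hi, size=n) for v, (lo, hi) in PROBE_SPANS.items()}
    )


def pairwise_auc(scores, labels) -> float:
    """Brute-force Mann-Whitney concordance: average over all
    positive-negative pairs of 1 (concordant) / 0.5 (tied) / 0."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def youden_scan(scores, labels, direction) -> float:
    """Exhaustive Youden scan over observed thresholds with the documented
    tie-breaks: max J, then max sensitivity, then smaller threshold.
    Exact rational arithmetic so ties are ties."""
    from fractions import Fraction

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for t in sorted(set(scores.tolist())):
        pred_pos = pos >= t if direction == "ge" else pos <= t
        pred_neg = neg >= t if direction == "ge" else neg <= t
        sens = Fraction(int(pred_pos.sum()), len(pos))
        spec = 1 - Fraction(int(pred_neg.sum()), len(neg))
        key = (sens + spec, sens, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])
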