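"""Cutoff derivation: sensitivity/specificity counting, exhaustive-scan
oracle equivalence, specificity-quantile recovery, the Welch screen."""

import numpy as np
import pandas as pd
import pytest

import booscore as bs
from booscore.derive import candidate_cutoffs
from booscore.errors import DerivationError, InputError, UndefinedMetricError


def make_cohort(pos_values, neg_values, variable="tpv"):
    return pd.DataFrame({
        variable: list(pos_values) + list(neg_values),
        "lutd_label": ["BPO"] * len(pos_values) + ["DO"] * len(neg_values),
    })


def oracle_rule_cutoffs(pos, neg, grid, direction):
    """Independent exhaustive scan over all finite candidates, replicating
    the documented selection: the least extreme cutoff whose specificity
    first reaches each target."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    cands = [c for c in candidate_cutoffs(np.concatenate([pos, neg])) if np.isfinite(c)]
    out = []
    for target in grid:
        qualifying = []
        for c in cands:
            spec = np.mean(neg < c) if direction == "ge" else np.mean(neg > c)
            if spec >= target - 1e-12:
                qualifying.append(c)
        if not qualifying:
            return None
        out.append(min(qualifying) if direction == "ge" else max(qualifying))
    return out


def test_sens_spec_hand_count():
    cohort = make_cohort([55, 45, 35, 25], [28, 31, 26, 29])
    perf = bs.variable_sens_spec(cohort, "tpv", cutoff=30, direction="ge")
    assert perf.sensitivity == pytest.approx(0.75)
    assert perf.specificity == pytest.approx(0.75)


def test_sens_spec_perfect_separation():
    cohort = make_cohort([5, 8, 10], [12, 15, 20], variable="qmax")
    perf = bs.variable_sens_spec(cohort, "qmax", cutoff=10, direction="le")
    assert perf.sensitivity == 1.0
    assert perf.specificity == 1.0


def test_sens_spec_single_class_errors():
    cohort = pd.DataFrame({"tpv": [1.0, 2.0], "lutd_label": ["BPO", "BND"]})
    with pytest.raises(UndefinedMetricError):
        bs.variable_sens_spec(cohort, "tpv", 1.5, "ge")


def test_sens_spec_extreme_cutoff_limits():
    cohort = make_cohort([55, 45], [20, 25])
    low = bs.variable_sens_spec(cohort, "tpv", -1e9, "ge")
    high = bs.variable_sens_spec(cohort, "tpv", 1e9, "ge")
    assert (low.sensitivity, low.specificity) == (1.0, 0.0)
    assert (high.sensitivity, high.specificity) == (0.0, 1.0)


@pytest.mark.parametrize("direction", ["ge", "le"])
@pytest.mark.parametrize("seed", range(30))
def test_derived_cutoffs_equal_exhaustive_scan(seed, direction):
    rng = np.random.default_rng(seed)
    m, n = rng.integers(4, 15, size=2)
    loc = 2.0 if direction == "ge" else -2.0
    pos = np.round(rng.normal(loc, 2, m), 1)
    neg = np.round(rng.normal(0, 2, n), 1)
    grid = (0.5, 0.8)
    expected = oracle_rule_cutoffs(pos, neg, grid, direction)
    cohort = make_cohort(pos, neg)
    try:
        rule = bs.derive_variable_rule(cohort, "tpv", 2, grid, direction)
    except DerivationError:
        # oracle must agree the targets are unreachable or collapse
        ordered = expected if (expected is None or direction == "ge") else expected[::-1]
        assert expected is None or any(
            b <= a for a, b in zip(ordered, ordered[1:])
        )
        return
    finite = sorted(
        {b.lower for b in rule.bins} | {b.upper for b in rule.bins} - {np.inf, -np.inf}
    )
    finite = [c for c in finite if np.isfinite(c)]
    want = sorted(expected)
    assert finite == pytest.approx(want)


def test_two_gaussian_specificity_quantile_recovery():
    rng = np.random.default_rng(314)
    pos = rng.normal(55, 5, 5000)
    neg = rng.normal(25, 5, 5000)
    cohort = make_cohort(pos, neg)
    grid = (0.60, 0.85, 0.92)
    rule = bs.derive_variable_rule(cohort, "tpv", 3, grid, "ge")
    cutoffs = sorted(b.lower for b in rule.bins if np.isfinite(b.lower))
    sorted_neg = np.sort(neg)
    for cut, target in zip(cutoffs, grid):
        # first-attainment contract: specificity reached at the cutoff ...
        assert np.mean(neg < cut) >= target
        # ... and within one candidate-grid step of the negative quantile
        q = np.quantile(neg, target)
        k = np.searchsorted(sorted_neg, cut)
        local_gap = sorted_neg[min(k + 1, len(neg) - 1)] - sorted_neg[max(k - 1, 0)]
        assert abs(cut - q) <= max(local_gap, 0.05)
    # bins award more points at higher values
    pts = [b.points for b in rule.bins]
    assert pts == sorted(pts) == [0, 1, 2, 3]


def test_degenerate_constant_variable_errors():
    cohort = make_cohort([3.0, 3.0, 3.0], [3.0, 3.0])
    with pytest.raises(DerivationError):
        bs.derive_variable_rule(cohort, "tpv", 1, (0.9,), "ge")


def test_single_target_perfect_separation():
    cohort = make_cohort([40, 50, 60], [10, 20, 30])
    rule = bs.derive_variable_rule(cohort, "tpv", 1, (0.99,), "ge")
    assert len(rule.bins) == 2
    cut = rule.bins[1].lower
    assert cut == pytest.approx(35.0)  # midpoint of 30 and 40
    assert [b.points for b in rule.bins] == [0, 1]


def test_unreachable_target_errors():
    # overlapping singleton values: max attainable specificity is 0.5
    cohort = make_cohort([1, 2], [1, 2])
    with pytest.raises(DerivationError):
        bs.derive_variable_rule(cohort, "tpv", 1, (0.999,), "ge")


def test_invalid_grids_rejected():
    cohort = make_cohort([40, 50], [10, 20])
    with pytest.raises(InputError):
        bs.derive_variable_rule(cohort, "tpv", 2, (0.9, 0.5), "ge")
    with pytest.raises(InputError):
        bs.derive_variable_rule(cohort, "tpv", 2, (0.5,), "ge")


def test_le_direction_mirrors_negated_ge():
    rng = np.random.default_rng(99)
    pos = rng.normal(-1, 1, 200)
    neg = rng.normal(1, 1, 200)
    cohort = make_cohort(pos, neg, variable="qmax")
    rule_le = bs.derive_variable_rule(cohort, "qmax", 2, (0.6, 0.8), "le")
    mirrored = make_cohort(-pos, -neg, variable="qmax")
    rule_ge = bs.derive_variable_rule(mirrored, "qmax", 2, (0.6, 0.8), "ge")
    cuts_le = sorted(b.upper for b in rule_le.bins if np.isfinite(b.upper))
    cuts_ge = sorted(-b.lower for b in rule_ge.bins if np.isfinite(b.lower))
    assert cuts_le == pytest.approx(cuts_ge)


def test_derived_rule_scores_all_reals():
    cohort = make_cohort([40, 50, 60, 45], [10, 20, 30, 15])
    rule = bs.derive_variable_rule(cohort, "tpv", 2, (0.5, 0.9), "ge")
    for v in (-1e6, 0.0, 33.3, 47.5, 1e6):
        assert bs.assign_points(v, rule) in (0, 1, 2)


def test_welch_screen_excludes_identical_groups():
    rng = np.random.default_rng(17)
    shared = rng.normal(0, 1, 300)
    separated = np.concatenate([rng.normal(3, 1, 300), rng.normal(0, 1, 300)])
    cohort = pd.DataFrame({
        "tpv": np.concatenate([shared, shared]),  # literally identical groups
        "qmax": separated,
        "lutd_label": ["BPO"] * 300 + ["DO"] * 300,
    })
    spec = {
        "tpv": (1, (0.8,), "ge"),
        "qmax": (1, (0.8,), "ge"),
    }
    card = bs.build_score_card(cohort, spec, screen=True)
    assert card.variables == ("qmax",)


def test_build_score_card_empty_spec():
    cohort = make_cohort([1, 2], [3, 4])
    card = bs.build_score_card(cohort, {})
    assert card.rules == ()
    assert bs.max_score(card) == 0


def test_build_score_card_ordering_invariant(default_cohort):
    spec = {
        "tpv": (3, (0.574, 0.851, 0.921), "ge"),
        "qmax": (3, (0.248, 0.356, 0.475), "le"),
    }
    card = bs.build_score_card(default_cohort, spec)
    tpv_cuts = [b.lower for b in card.rule("tpv").bins if np.isfinite(b.lower)]
    assert tpv_cuts == sorted(tpv_cuts)
    qmax_rule = card.rule("qmax")
    # the top-points qmax cutoff sits at or below the 1-point cutoff
    uppers = [b.upper for b in qmax_rule.bins if np.isfinite(b.upper)]
    assert uppers == sorted(uppers)
    assert [b.points for b in qmax_rule.bins] == [3, 2, 1, 0]
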