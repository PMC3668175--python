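"""2x2 diagnostic statistics: proportions, odds ratios, Fisher test, CIs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom
from statsmodels.stats.proportion import proportion_confint

from thyroscore import (
    ContingencyTable,
    USFeatureProfile,
    compute_metrics,
    feature_performance_table,
    fisher_exact,
    npv,
    odds_ratio,
    ppv,
    sensitivity,
    specificity,
)
from thyroscore.config import StatsConfig
from thyroscore.stats import UndefinedMetricError


# ------------------------------------------------------------ proportions

@pytest.mark.parametrize(
    "table, sens, spec, ppv_, npv_",
    [
        (ContingencyTable(96, 4, 54, 46), 96.0, 46.0, 64.0, 92.0),   # vascularity
        (ContingencyTable(86, 14, 2, 98), 86.0, 98.0, None, None),   # orientation
        (ContingencyTable(10, 0, 0, 10), 100.0, 100.0, 100.0, 100.0),
    ],
)
def test_point_estimates(table, sens, spec, ppv_, npv_):
    assert sensitivity(table).percent == pytest.approx(sens)
    assert specificity(table).percent == pytest.approx(spec)
    if ppv_ is not None:
        assert ppv(table).percent == pytest.approx(ppv_)
    if npv_ is not None:
        assert npv(table).percent == pytest.approx(npv_)


def test_confidence_intervals_consistent_with_published_style():
    """Exact binomial CIs agree with the reference performance table's
    integer intervals for the vascularity counts to within one unit in the
    last printed digit (the published table's own integer rounding is not a
    single consistent rule)."""
    t = ContingencyTable(96, 4, 54, 46)
    m = compute_metrics(t)
    published = {
        "sensitivity": (90, 99),
        "specificity": (36, 56),
        "ppv": (56, 72),
        "npv": (80, 98),
    }
    for name, (lo, hi) in published.items():
        est = getattr(m, name)
        assert abs(est.ci_low - lo) <= 1.0
        assert abs(est.ci_high - hi) <= 1.0


def test_zero_denominator_raises_named_error():
    with pytest.raises(UndefinedMetricError, match="sensitivity"):
        sensitivity(ContingencyTable(0, 0, 5, 5))
    with pytest.raises(UndefinedMetricError, match="PPV"):
        ppv(ContingencyTable(0, 5, 0, 5))


def test_wilson_alternative_ci_method():
    cfg = StatsConfig(ci_method="wilson")
    est = sensitivity(ContingencyTable(96, 4, 54, 46), cfg)
    lo, hi = proportion_confint(96, 100, method="wilson")
    assert est.ci_low == pytest.approx(100 * lo)
    assert est.ci_high == pytest.approx(100 * hi)


tables = st.tuples(*[st.integers(0, 80)] * 4).map(lambda t: ContingencyTable(*t))


@given(table=tables)
@settings(max_examples=60, deadline=None)
def test_ci_contains_point_estimate(table):
    for metric in (sensitivity, specificity, ppv, npv):
        try:
            est = metric(table)
        except UndefinedMetricError:
            continue
        assert est.ci_low - 1e-9 <= est.percent <= est.ci_high + 1e-9
        assert 0.0 <= est.percent <= 100.0


# ------------------------------------------------------------ odds ratio

@pytest.mark.parametrize(
    "table, expected",
    [
        (ContingencyTable(86, 14, 2, 98), 301.0),
        (ContingencyTable(93, 7, 35, 65), 24.67),
        (ContingencyTable(96, 4, 54, 46), 20.44),
        (ContingencyTable(84, 16, 22, 78), 18.61),
        (ContingencyTable(77, 23, 30, 70), 7.81),
        (ContingencyTable(76, 24, 35, 65), 5.88),
        (ContingencyTable(94, 6, 79, 21), 4.16),
        (ContingencyTable(7, 7, 7, 7), 1.0),
    ],
)
def test_odds_ratio_point_estimates(table, expected):
    assert round(odds_ratio(table).value, 2) == expected


def test_odds_ratio_ci_brackets_estimate_and_is_woolf():
    t = ContingencyTable(86, 14, 2, 98)
    est = odds_ratio(t)
    assert est.ci_low < est.value < est.ci_high
    se = np.sqrt(1 / 86 + 1 / 14 + 1 / 2 + 1 / 98)
    assert est.ci_low == pytest.approx(est.value * np.exp(-1.959963985 * se))


def test_zero_cell_policies():
    t = ContingencyTable(10, 0, 5, 5)
    est = odds_ratio(t)  # default: Haldane-Anscombe
    assert est.corrected
    assert est.value == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))
    with pytest.raises(UndefinedMetricError):
        odds_ratio(t, StatsConfig(or_zero_policy="error"))


@given(table=st.tuples(*[st.integers(1, 200)] * 4).map(lambda t: ContingencyTable(*t)))
@settings(max_examples=100, deadline=None)
def test_row_swap_reciprocity(table):
    assert odds_ratio(table).value * odds_ratio(table.swap_rows()).value == pytest.approx(1.0)


# ------------------------------------------------------------ Fisher test

def _fisher_oracle(t: ContingencyTable) -> float:
    """Brute-force two-sided Fisher p: sum hypergeometric probabilities of
    all same-margin tables no more likely than the observed one."""
    if t.n == 0:
        return 1.0
    n, row1, col1 = t.n, t.tp + t.fp, t.tp + t.fn
    rv = hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    observed = rv.pmf(t.tp)
    return float(probs[probs <= observed * (1 + 1e-9)].sum())


@given(table=st.tuples(*[st.integers(0, 8)] * 4).map(lambda t: ContingencyTable(*t)))
@settings(max_examples=150, deadline=None)
def test_fisher_matches_brute_force_enumeration(table):
    assert fisher_exact(table) == pytest.approx(_fisher_oracle(table), abs=1e-12)


def test_fisher_examples():
    p = fisher_exact(ContingencyTable(94, 6, 79, 21))
    assert p == pytest.approx(0.003, abs=0.001)  # soft order-of-magnitude check
    assert p < 0.05
    assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)
    assert fisher_exact(ContingencyTable(86, 14, 2, 98)) < 1e-4


# --------------------------------------------------- cohort-level metrics

def test_feature_performance_reproduces_reference_tables(study_tables):
    from thyroscore.cohort import exact_cohort_from_counts

    cohort = exact_cohort_from_counts(study_tables)
    metrics = feature_performance_table(cohort)
    assert list(metrics) == ["V", "C1", "O", "C2", "E", "M", "H"]
    for code, t in study_tables.items():
        m = metrics[code]
        assert m.sensitivity.percent == pytest.approx(100 * t.tp / (t.tp + t.fn))
        assert m.specificity.percent == pytest.approx(100 * t.tn / (t.fp + t.tn))


def test_feature_performance_rejects_degenerate_cohorts():
    p = USFeatureProfile()
    with pytest.raises(ValueError):
        feature_performance_table([])
    with pytest.raises(ValueError):
        feature_performance_table([(p, True), (p, True)])


def test_identical_profiles_give_unit_odds_ratio_after_correction():
    p = USFeatureProfile.from_codes(E=True)
    metrics = feature_performance_table([(p, True), (p, False)])
    for m in metrics.values():
        assert m.odds_ratio.value == pytest.approx(1.0)
        assert m.odds_ratio.corrected
    # features with no positive record have an undefined PPV, not a crash
    assert metrics["V"].ppv is None
    assert metrics["E"].ppv is not None


def test_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 0)
    with pytest.raises(ValueError):
        ContingencyTable(1.5, 0, 0, 0)  # type: ignore[arg-type]
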