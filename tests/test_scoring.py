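"""Scoring: point weights, risk stratification, derived-feature rules."""

from __future__ import annotations

import datetime

import pytest
from hypothesis import given, strategies as st

from thyroscore import (
    MAX_SCORE,
    NoduleMeasurement,
    RiskCategory,
    USFeatureProfile,
    detect_rapid_growth,
    diameter_criterion,
    score_profile,
    stratify_risk,
)
from thyroscore.config import ScoringConfig
from thyroscore.features import FEATURE_CODES

D0 = datetime.date(2020, 1, 1)


def _m(dims, months):
    return NoduleMeasurement(dims_mm=tuple(dims), date=D0 + datetime.timedelta(days=int(30.44 * months)))


# ---------------------------------------------------------------- scoring

def test_worked_examples_score_and_stratify(worked_examples):
    for profile, total, risk in worked_examples:
        res = score_profile(profile)
        assert res.total == total
        assert res.risk is risk
        assert sum(res.breakdown.values()) == res.total


@pytest.mark.parametrize(
    "codes, total",
    [({}, 0.0), (dict.fromkeys(FEATURE_CODES, True), MAX_SCORE)],
    ids=["empty", "saturated"],
)
def test_extreme_profiles(codes, total):
    res = score_profile(USFeatureProfile.from_codes(codes))
    assert res.total == total
    assert res.risk is (RiskCategory.LOW if total == 0 else RiskCategory.HIGH)


def test_major_feature_combinations():
    """Growth or lymph nodes alone stay LOW; together INTERMEDIATE; plus any
    1-point feature HIGH — exact consequences of the weight table."""
    g = USFeatureProfile.from_codes(G=True)
    l = USFeatureProfile.from_codes(L=True)
    gl = USFeatureProfile.from_codes(G=True, L=True)
    glo = USFeatureProfile.from_codes(G=True, L=True, O=True)
    assert (score_profile(g).total, score_profile(g).risk) == (3.0, RiskCategory.LOW)
    assert (score_profile(l).total, score_profile(l).risk) == (3.0, RiskCategory.LOW)
    assert (score_profile(gl).total, score_profile(gl).risk) == (6.0, RiskCategory.INTERMEDIATE)
    assert (score_profile(glo).total, score_profile(glo).risk) == (7.0, RiskCategory.HIGH)


# hard-coded oracle: every attainable half-point total and its category
RISK_ORACLE = {
    **{t / 2: RiskCategory.LOW for t in range(0, 8)},          # 0 .. 3.5
    **{t / 2: RiskCategory.INTERMEDIATE for t in range(8, 14)},  # 4 .. 6.5
    **{t / 2: RiskCategory.HIGH for t in range(14, 25)},         # 7 .. 12
}


def test_half_point_sweep_matches_oracle():
    for total, expected in RISK_ORACLE.items():
        assert stratify_risk(total) is expected, total


def test_stratify_rejects_invalid_totals():
    with pytest.raises(ValueError):
        stratify_risk(-0.5)
    with pytest.raises(ValueError):
        stratify_risk(1.3)


profiles = st.fixed_dictionaries({c: st.booleans() for c in FEATURE_CODES})


@given(profile=profiles, flip=st.sampled_from(FEATURE_CODES))
def test_flipping_a_feature_on_never_lowers_score_or_risk(profile, flip):
    base = dict(profile, **{flip: False})
    raised = dict(profile, **{flip: True})
    r0 = score_profile(USFeatureProfile.from_codes(base))
    r1 = score_profile(USFeatureProfile.from_codes(raised))
    order = [RiskCategory.LOW, RiskCategory.INTERMEDIATE, RiskCategory.HIGH]
    assert r1.total >= r0.total
    assert order.index(r1.risk) >= order.index(r0.risk)


@given(profile=profiles)
def test_score_is_additive_over_single_features(profile):
    combined = score_profile(USFeatureProfile.from_codes(profile)).total
    singles = sum(
        score_profile(USFeatureProfile.from_codes({c: True})).total
        for c, v in profile.items()
        if v
    )
    assert combined == singles


def test_profile_rejects_non_boolean_values():
    with pytest.raises(TypeError):
        USFeatureProfile(hypoechogenic=1)  # type: ignore[arg-type]
    with pytest.raises(KeyError):
        USFeatureProfile.from_codes(X=True)


def test_custom_weights_change_totals():
    cfg = ScoringConfig(weights={**ScoringConfig().weights, "E": 2.0})
    assert score_profile(USFeatureProfile.from_codes(E=True), cfg).total == 2.0


# ---------------------------------------------------------- rapid growth

@pytest.mark.parametrize(
    "earlier, later, months, expected",
    [
        ((10, 10, 10), (12, 12, 10), 12, True),   # two dims +20% and +2 mm
        ((10, 10, 10), (12, 12, 12), 20, False),  # window not < 18 months
        ((5, 5, 5), (6, 6, 6), 6, False),         # 20% met but only 1 mm
        ((10, 10, 10), (10, 10, 10), 1, False),   # no growth at all
        ((10, 10, 10), (12, 10, 10), 6, False),   # only one dimension grew
        # sorted pairing: (30,20,10)->(36,24,12), all +20% and >= 2 mm
        ((10, 20, 30), (36, 12, 24), 6, True),
    ],
)
def test_rapid_growth_rule(earlier, later, months, expected):
    assert detect_rapid_growth(_m(earlier, 0), _m(later, months)) is expected


def test_rapid_growth_axis_pairing_differs_from_sorted():
    # one axis ballooned: axis-wise that is a single grown dimension, but
    # sorted pairing redistributes it over two
    earlier, later = _m((10, 20, 20), 0), _m((25, 20, 20), 6)
    assert detect_rapid_growth(earlier, later, pair_by="axis") is False
    assert detect_rapid_growth(earlier, later, pair_by="sorted") is True
    grown = _m((13, 25, 20), 6)
    assert detect_rapid_growth(earlier, grown, pair_by="axis") is True


def test_rapid_growth_window_boundary_is_strict():
    cfg = ScoringConfig()
    at_window = NoduleMeasurement((12, 12, 12), D0 + datetime.timedelta(days=cfg.growth_window_days))
    inside = NoduleMeasurement((12, 12, 12), D0 + datetime.timedelta(days=cfg.growth_window_days - 1))
    start = NoduleMeasurement((10, 10, 10), D0)
    assert detect_rapid_growth(start, at_window) is False
    assert detect_rapid_growth(start, inside) is True


def test_rapid_growth_rejects_bad_intervals():
    with pytest.raises(ValueError):
        detect_rapid_growth(_m((10, 10, 10), 6), _m((12, 12, 12), 0))
    with pytest.raises(ValueError):
        detect_rapid_growth(_m((10, 10, 10), 0), _m((12, 12, 12), 0))


# ----------------------------------------------------- diameter criterion

@pytest.mark.parametrize(
    "dims, expected",
    [((31, 10, 10), True), ((30, 30, 30), False), ((12, 8, 6), False)],
)
def test_diameter_criterion_strict_cutoff(dims, expected):
    assert diameter_criterion(dims) is expected


def test_diameter_criterion_validates_dimensions():
    with pytest.raises(ValueError):
        diameter_criterion((10, 10))
    with pytest.raises(ValueError):
        diameter_criterion((10, -1, 10))


def test_measurement_validation():
    with pytest.raises(ValueError):
        NoduleMeasurement((0, 10, 10), D0)
    with pytest.raises(ValueError):
        NoduleMeasurement((10, 10), D0)
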