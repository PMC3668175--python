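"""Shared fixtures: worked-example profiles, reference tables, and the
hand-written management oracle."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thyroscore import RiskCategory, TBSRTCCategory, USFeatureProfile
from thyroscore.management import ManagementAction
from thyroscore.reference import STUDY_FEATURE_TABLES


@pytest.fixture(scope="session")
def worked_examples() -> list[tuple[USFeatureProfile, float, RiskCategory]]:
    """The three published worked scoring examples (profile, total, risk)."""
    return [
        # hypoechogenic solid nodule, nothing else suspicious
        (USFeatureProfile.from_codes(E=True, C2=True), 1.5, RiskCategory.LOW),
        # microcalcifications, taller-than-wide, hypoechoic, intranodular flow,
        # absent halo, solid, irregular margin; < 3 cm, no growth, no nodes
        (
            USFeatureProfile.from_codes(
                C1=True, O=True, E=True, V=True, H=True, C2=True, M=True
            ),
            5.5,
            RiskCategory.INTERMEDIATE,
        ),
        # as above but not taller-than-wide, with a metastatic cervical node
        (
            USFeatureProfile.from_codes(
                C1=True, V=True, E=True, H=True, C2=True, M=True, L=True
            ),
            7.5,
            RiskCategory.HIGH,
        ),
    ]


@pytest.fixture(scope="session")
def study_tables():
    """Development-cohort 2x2 counts for the seven evaluated features."""
    return STUDY_FEATURE_TABLES


_O, _R, _S, _U = (
    ManagementAction.OBSERVE,
    ManagementAction.REPEAT_FNAB,
    ManagementAction.SURGERY,
    ManagementAction.URGENT_SURGERY,
)
_LOW, _INT, _HIGH = RiskCategory.LOW, RiskCategory.INTERMEDIATE, RiskCategory.HIGH


@pytest.fixture(scope="session")
def management_oracle() -> dict[tuple[RiskCategory, TBSRTCCategory, bool], ManagementAction]:
    """Hand-written expected action for every (US risk, cytology, us-changed) cell.

    Encodes: V/VI -> urgent surgery always; IV -> surgery, except a changed
    ultrasound pattern warrants re-biopsy first (unless high-risk US keeps
    surgery); III and I -> repeat biopsy, escalated to surgery by a
    high-risk pattern; II -> observe, escalated to repeat biopsy by an
    intermediate-risk pattern and to surgery by a high-risk pattern.
    """
    table: dict[tuple[RiskCategory, TBSRTCCategory, bool], ManagementAction] = {}
    for changed in (False, True):
        for risk in (_LOW, _INT, _HIGH):
            table[(risk, TBSRTCCategory.VI, changed)] = _U
            table[(risk, TBSRTCCategory.V, changed)] = _U
            table[(risk, TBSRTCCategory.IV, changed)] = (
                (_R if risk is not _HIGH else _S) if changed else _S
            )
            for cyt in (TBSRTCCategory.III, TBSRTCCategory.I):
                table[(risk, cyt, changed)] = _R if risk is not _HIGH else _S
            table[(risk, TBSRTCCategory.II, changed)] = {_LOW: _O, _INT: _R, _HIGH: _S}[risk]
    return table
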