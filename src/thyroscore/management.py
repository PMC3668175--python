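"""Management recommendations from ultrasound risk, Bethesda cytology, and
clinical flags.

The decision combines two independent readings of the nodule:

* the cytology category (TBSRTC I-VI) fixes a *base* action — malignant or
  suspicious cytology (V, VI) means urgent referral for surgery; a follicular
  neoplasm (IV) means surgery, with a repeat biopsy instead only when the
  ultrasound pattern has changed since the aspirate; indeterminate or
  nondiagnostic results (III, I) mean a repeat biopsy; benign cytology (II)
  means observation;
* the ultrasound risk pattern imposes a *floor* — benign cytology carries a
  false-negative risk of up to ~3%, so an intermediate-risk pattern raises
  observation to a repeat biopsy and a high-risk pattern raises it to
  surgery.

The recommendation is the more severe of the two.  Clinical malignancy
predictors (age <20 or >60, male sex, neck irradiation, family history,
alarm symptoms such as non-laryngeal hoarseness, tumour ache or dysphagia)
are advisory: they are appended to the audit trail and may upgrade plain
observation to a repeat biopsy, but never downgrade an action.

The full rule table ships as an editable, versioned configuration
(:class:`thyroscore.config.ManagementConfig`); the defaults implement the
reconstruction described above, which is this package's codification of the
published management algorithm, not a verbatim transcription of it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .config import DEFAULT_CONFIG, ManagementConfig
from .reference import TBSRTC_DESCRIPTIONS, TBSRTC_RISK
from .scoring import RiskCategory, risk_rank

__all__ = [
    "ManagementAction",
    "TBSRTCCategory",
    "ClinicalFlags",
    "ManagementRecommendation",
    "recommend_management",
    "action_severity",
    "cytology_severity_rank",
]


class ManagementAction(enum.Enum):
    OBSERVE = "OBSERVE"
    REPEAT_FNAB = "REPEAT_FNAB"
    SURGERY = "SURGERY"
    URGENT_SURGERY = "URGENT_SURGERY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SEVERITY = {
    ManagementAction.OBSERVE: 0,
    ManagementAction.REPEAT_FNAB: 1,
    ManagementAction.SURGERY: 2,
    ManagementAction.URGENT_SURGERY: 3,
}


def action_severity(action: ManagementAction) -> int:
    """OBSERVE < REPEAT_FNAB < SURGERY < URGENT_SURGERY."""
    return _SEVERITY[action]


class TBSRTCCategory(enum.Enum):
    """Bethesda cytology category with its published malignancy-risk range."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"

    @property
    def malignancy_risk_range(self) -> tuple[float, float]:
        """Published malignancy risk for the category, percent (low, high)."""
        return TBSRTC_RISK[self.value]

    @property
    def description(self) -> str:
        return TBSRTC_DESCRIPTIONS[self.value]

    @classmethod
    def parse(cls, text: str) -> "TBSRTCCategory":
        t = str(text).strip().upper()
        try:
            return cls[t]
        except KeyError:
            raise ValueError(f"invalid TBSRTC category {text!r}; expected I-VI") from None


#: Expected-severity ordering of cytology categories (II mildest; I and III
#: are equivalent in expected management; VI most severe).
_CYTOLOGY_RANK = {
    TBSRTCCategory.II: 0,
    TBSRTCCategory.I: 1,
    TBSRTCCategory.III: 1,
    TBSRTCCategory.IV: 2,
    TBSRTCCategory.V: 3,
    TBSRTCCategory.VI: 3,
}


def cytology_severity_rank(category: TBSRTCCategory) -> int:
    return _CYTOLOGY_RANK[category]


@dataclass(frozen=True, slots=True)
class ClinicalFlags:
    """Clinical malignancy predictors; ``None`` means unknown."""

    age_years: Optional[int] = None
    male_sex: Optional[bool] = None
    neck_irradiation_history: Optional[bool] = None
    family_history: Optional[bool] = None
    alarm_symptoms: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    def positive(self) -> list[str]:
        """Identifiers of the flags that are present."""
        out = []
        if self.age_years is not None and (self.age_years < 20 or self.age_years > 60):
            out.append("FLAG_AGE_EXTREME")
        if self.male_sex:
            out.append("FLAG_MALE_SEX")
        if self.neck_irradiation_history:
            out.append("FLAG_NECK_IRRADIATION")
        if self.family_history:
            out.append("FLAG_FAMILY_HISTORY")
        if self.alarm_symptoms:
            out.append("FLAG_ALARM_SYMPTOMS")
        return out


@dataclass(frozen=True)
class ManagementRecommendation:
    action: ManagementAction
    repeat_interval_months: Optional[int]
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("rationale must cite at least one rule")
        needs_interval = self.action in (ManagementAction.OBSERVE, ManagementAction.REPEAT_FNAB)
        if needs_interval != (self.repeat_interval_months is not None):
            raise ValueError("interval present iff action is OBSERVE or REPEAT_FNAB")
        if self.repeat_interval_months is not None and self.repeat_interval_months <= 0:
            raise ValueError("repeat interval must be positive")


def _base_action(
    cytology: TBSRTCCategory, us_pattern_changed: bool, config: ManagementConfig
) -> tuple[ManagementAction, str]:
    key = cytology.value
    rule = f"CYT_{key}"
    if cytology is TBSRTCCategory.IV and us_pattern_changed:
        key, rule = "IV_US_CHANGED", "CYT_IV_US_CHANGED"
    return ManagementAction(config.cytology_base[key]), rule


def recommend_management(
    risk: RiskCategory,
    cytology: TBSRTCCategory,
    flags: ClinicalFlags | None = None,
    us_pattern_changed: bool = False,
    config: ManagementConfig | None = None,
) -> ManagementRecommendation:
    """Recommend management for one nodule.

    Parameters
    ----------
    risk
        Ultrasound risk pattern (from the total score).
    cytology
        Bethesda category of the most recent FNAB.
    flags
        Clinical malignancy predictors; omitted flags mean unknown.
    us_pattern_changed
        Whether the ultrasound pattern changed versus the prior examination
        (relevant to category IV, where a repeat biopsy is otherwise futile).
    """
    config = config or DEFAULT_CONFIG.management
    flags = flags or ClinicalFlags()

    action, base_rule = _base_action(cytology, us_pattern_changed, config)
    rationale = [base_rule]

    floor = ManagementAction(config.risk_floor[risk.value])
    if action_severity(floor) > action_severity(action):
        action = floor
        rationale.append(f"US_{risk.value}_ESCALATES")

    flag_ids = flags.positive()
    rationale.extend(flag_ids)
    if (
        flag_ids
        and config.flags_upgrade_observation
        and action is ManagementAction.OBSERVE
    ):
        action = ManagementAction.REPEAT_FNAB
        rationale.append("FLAGS_UPGRADE_OBSERVATION")

    if action is ManagementAction.OBSERVE:
        interval = config.observe_interval_months
    elif action is ManagementAction.REPEAT_FNAB:
        interval = config.repeat_fnab_interval_months
    else:
        interval = None
    return ManagementRecommendation(
        action=action, repeat_interval_months=interval, rationale=tuple(rationale)
    )
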