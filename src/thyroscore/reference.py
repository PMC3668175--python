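"""Reference data shipped with the package.

``STUDY_FEATURE_TABLES`` holds the per-feature 2x2 counts from the
development cohort of the scoring system (100 histologically malignant and
100 benign thyroid focal lesions; the seven evaluated ultrasound
characteristics).  Raw counts are authoritative; the percentage annotations
that sometimes accompany such published tables are never consumed.

``TBSRTC_RISK`` holds the Bethesda System for Reporting Thyroid
Cytopathology categories with their published malignancy-risk ranges
(percent).
"""

from __future__ import annotations

from .stats import ContingencyTable

#: Development-cohort 2x2 counts: feature-positive/negative x malignant/benign.
STUDY_FEATURE_TABLES: dict[str, ContingencyTable] = {
    "V": ContingencyTable(tp=96, fn=4, fp=54, tn=46),
    "C1": ContingencyTable(tp=93, fn=7, fp=35, tn=65),
    "O": ContingencyTable(tp=86, fn=14, fp=2, tn=98),
    "C2": ContingencyTable(tp=94, fn=6, fp=79, tn=21),
    "E": ContingencyTable(tp=84, fn=16, fp=22, tn=78),
    "M": ContingencyTable(tp=77, fn=23, fp=30, tn=70),
    "H": ContingencyTable(tp=76, fn=24, fp=35, tn=65),
}

#: Class-conditional feature prevalences implied by the development cohort:
#: code -> (P(feature | malignant), P(feature | benign)).  Rapid growth (G),
#: pathologic lymph nodes (L) and diameter > 3 cm (D) default to zero
#: prevalence: in the development cohort abnormal lymph nodes occurred only
#: with malignant foci (and were excluded from statistics), growth could not
#: be followed, and no lesion exceeded 3 cm.
STUDY_PREVALENCES: dict[str, tuple[float, float]] = {
    **{
        code: (t.tp / (t.tp + t.fn), t.fp / (t.fp + t.tn))
        for code, t in STUDY_FEATURE_TABLES.items()
    },
    "G": (0.0, 0.0),
    "L": (0.0, 0.0),
    "D": (0.0, 0.0),
}

#: Bethesda (TBSRTC) categories -> published malignancy risk range, percent.
TBSRTC_RISK: dict[str, tuple[float, float]] = {
    "I": (1.0, 4.0),
    "II": (0.0, 3.0),
    "III": (5.0, 15.0),
    "IV": (15.0, 30.0),
    "V": (60.0, 75.0),
    "VI": (97.0, 99.0),
}

TBSRTC_DESCRIPTIONS: dict[str, str] = {
    "I": "Nondiagnostic or unsatisfactory",
    "II": "Benign",
    "III": "Atypia / follicular lesion of undetermined significance",
    "IV": "Follicular neoplasm or suspicious for a follicular neoplasm",
    "V": "Suspicious for malignancy",
    "VI": "Malignant",
}
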