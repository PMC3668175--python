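"""Domain types for thyroid-nodule ultrasound features.

The scoring system works on ten binary characteristics read from the
ultrasound examination.  Each carries the letter code used throughout
reports and I/O:

========  =====================================================================
``G``     rapid growth of the nodule (>=20% in two dimensions, >=2 mm, <18 mo)
``L``     pathologically altered cervical lymph nodes
``O``     "taller-than-wide" orientation in transverse and/or longitudinal plane
``C1``    microcalcifications (alone or coexisting with other calcifications)
``V``     abnormal vascularity: increased intranodular flow, or completely
          absent flow in a hypoechogenic solid lesion (peripheral flow = false)
``E``     hypoechogenicity (echogenicity reduced to muscle level)
``M``     blurred, poorly defined margin
``H``     halo absent, or an irregular rim of uneven thickness
``C2``    solid composition (cystic component <=10% of volume counts as solid)
``D``     largest diameter strictly greater than 3.0 cm
========  =====================================================================

All ten fields must be explicit booleans at scoring time; how missing CSV
cells are resolved is an I/O-layer policy (see :mod:`thyroscore.io`), never
a silent default here.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass

#: Feature codes in canonical (report) order: most important, major, minor.
FEATURE_CODES: tuple[str, ...] = ("G", "L", "O", "C1", "V", "E", "M", "H", "C2", "D")

#: Mapping feature code -> USFeatureProfile attribute name.
FEATURE_FIELDS: dict[str, str] = {
    "G": "growth_rapid",
    "L": "lymph_nodes_pathologic",
    "O": "orientation_taller_than_wide",
    "C1": "microcalcifications",
    "V": "vascularity_abnormal",
    "E": "hypoechogenic",
    "M": "margin_irregular",
    "H": "halo_absent_or_irregular",
    "C2": "composition_solid",
    "D": "diameter_over_3cm",
}

#: The seven features that were statistically evaluated against histology,
#: in the order the diagnostic-performance report prints them.
EVALUATED_FEATURES: tuple[str, ...] = ("V", "C1", "O", "C2", "E", "M", "H")

FEATURE_NAMES: dict[str, str] = {
    "G": "Rapid growth",
    "L": "Pathologic lymph nodes",
    "O": "Orientation (taller-than-wide)",
    "C1": "Microcalcifications",
    "V": "Vascularity (intranodular/absent)",
    "E": "Echogenicity (hypoechogenic)",
    "M": "Margins (irregular)",
    "H": "Peripheral halo (absent/irregular)",
    "C2": "Composition (solid)",
    "D": "Diameter (> 3.0 cm)",
}


@dataclass(frozen=True, slots=True)
class USFeatureProfile:
    """The ten scoreable ultrasound characteristics of one nodule.

    Every field is a plain boolean; construction rejects anything else so
    that a half-parsed record can never reach the scorer.
    """

    growth_rapid: bool = False
    lymph_nodes_pathologic: bool = False
    orientation_taller_than_wide: bool = False
    microcalcifications: bool = False
    vascularity_abnormal: bool = False
    hypoechogenic: bool = False
    margin_irregular: bool = False
    halo_absent_or_irregular: bool = False
    composition_solid: bool = False
    diameter_over_3cm: bool = False

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, bool):
                raise TypeError(
                    f"feature {f.name!r} must be an explicit bool, got {v!r}; "
                    "resolve missing values upstream (see io missing_policy)"
                )

    @classmethod
    def from_codes(cls, codes: dict[str, bool] | None = None, /, **kw: bool) -> "USFeatureProfile":
        """Build a profile from letter codes, e.g. ``from_codes(E=True, C2=True)``.

        Unmentioned features default to False (absent).
        """
        merged = dict(codes or {})
        merged.update(kw)
        unknown = set(merged) - set(FEATURE_CODES)
        if unknown:
            raise KeyError(f"unknown feature code(s): {sorted(unknown)}")
        return cls(**{FEATURE_FIELDS[c]: bool(v) for c, v in merged.items()})

    def code_values(self) -> dict[str, bool]:
        """Feature values keyed by letter code, in canonical order."""
        return {c: getattr(self, FEATURE_FIELDS[c]) for c in FEATURE_CODES}


@dataclass(frozen=True, slots=True)
class NoduleMeasurement:
    """Three orthogonal nodule dimensions (mm) at one dated examination."""

    dims_mm: tuple[float, float, float]
    date: datetime.date

    def __post_init__(self) -> None:
        dims = tuple(float(d) for d in self.dims_mm)
        if len(dims) != 3:
            raise ValueError(f"exactly three dimensions required, got {len(dims)}")
        if any(d <= 0 for d in dims):
            raise ValueError(f"dimensions must be positive, got {dims}")
        object.__setattr__(self, "dims_mm", dims)
        if not isinstance(self.date, datetime.date) or isinstance(self.date, datetime.datetime):
            if isinstance(self.date, datetime.datetime):
                object.__setattr__(self, "date", self.date.date())
            else:
                raise TypeError("date must be a datetime.date")
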