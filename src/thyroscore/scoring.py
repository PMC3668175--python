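"""The ultrasound risk score: point assignment, risk stratification, and
the derived-feature rules (rapid growth, diameter criterion).

The score sums feature weights over the ten characteristics:

* 3 points each: rapid growth (G), pathologic cervical lymph nodes (L)
* 1 point each: taller-than-wide orientation (O), microcalcifications (C1),
  abnormal vascularity (V), hypoechogenicity (E)
* 0.5 points each: irregular margin (M), absent/irregular halo (H),
  solid composition (C2), diameter > 3 cm (D)

Totals map to an ultrasound risk pattern: LOW for 0 <= total < 4,
INTERMEDIATE for 4 <= total < 7, HIGH for total >= 7.  Arithmetic is done
in half-point integer units so the 4- and 7-point boundaries are exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .config import DEFAULT_CONFIG, ScoringConfig
from .features import FEATURE_CODES, NoduleMeasurement, USFeatureProfile

__all__ = [
    "RiskCategory",
    "ScoreResult",
    "score_profile",
    "stratify_risk",
    "detect_rapid_growth",
    "diameter_criterion",
    "MAX_SCORE",
]

#: Maximum attainable total with the default weights (3+3 + 4*1 + 4*0.5).
MAX_SCORE = 12.0


class RiskCategory(enum.Enum):
    """Ultrasound risk pattern derived from the total score."""

    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ordering used by the management engine's monotonicity guarantees
_RISK_ORDER = {RiskCategory.LOW: 0, RiskCategory.INTERMEDIATE: 1, RiskCategory.HIGH: 2}


def risk_rank(risk: RiskCategory) -> int:
    return _RISK_ORDER[risk]


@dataclass(frozen=True)
class ScoreResult:
    """Total score, per-feature point breakdown, and risk category."""

    total: float
    breakdown: dict[str, float]
    risk: RiskCategory

    def __post_init__(self) -> None:
        if abs(sum(self.breakdown.values()) - self.total) > 1e-9:
            raise ValueError("breakdown does not sum to total")


def stratify_risk(total: float, config: ScoringConfig | None = None) -> RiskCategory:
    """Map a total score (points) to its risk category.

    Boundaries are half-open: LOW [0, 4), INTERMEDIATE [4, 7), HIGH [7, inf).
    """
    config = config or DEFAULT_CONFIG.scoring
    if total < 0:
        raise ValueError(f"total score cannot be negative, got {total}")
    doubled = total * 2
    if abs(doubled - round(doubled)) > 1e-9:
        raise ValueError(f"total score must be a multiple of 0.5, got {total}")
    half = int(round(doubled))
    lo, hi = config.bounds_half_units
    if half < lo:
        return RiskCategory.LOW
    if half < hi:
        return RiskCategory.INTERMEDIATE
    return RiskCategory.HIGH


def score_profile(profile: USFeatureProfile, config: ScoringConfig | None = None) -> ScoreResult:
    """Score a fully specified feature profile.

    Returns the total (a non-negative multiple of 0.5), the per-feature
    breakdown keyed by letter code, and the risk category.
    """
    config = config or DEFAULT_CONFIG.scoring
    values = profile.code_values()
    half_breakdown = {c: (config.weight_half_units(c) if values[c] else 0) for c in FEATURE_CODES}
    total_half = sum(half_breakdown.values())
    total = total_half / 2.0
    return ScoreResult(
        total=total,
        breakdown={c: h / 2.0 for c, h in half_breakdown.items()},
        risk=stratify_risk(total, config),
    )


def _paired_growth(earlier: Sequence[float], later: Sequence[float]) -> list[tuple[float, float]]:
    return list(zip(earlier, later))


def detect_rapid_growth(
    earlier: NoduleMeasurement,
    later: NoduleMeasurement,
    *,
    pair_by: str = "sorted",
    config: ScoringConfig | None = None,
) -> bool:
    """Decide whether serial measurements establish rapid growth (feature G).

    True iff the interval is shorter than 18 months (548 days) and at least
    two of the three paired dimensions each grew by >=20% of the earlier
    value and by >=2 mm absolutely.

    ``pair_by="sorted"`` (default) pairs dimensions largest-to-largest,
    appropriate when serial scans do not preserve axis identity;
    ``pair_by="axis"`` compares dimensions position-wise as given.
    """
    config = config or DEFAULT_CONFIG.scoring
    if pair_by not in ("sorted", "axis"):
        raise ValueError(f"pair_by must be 'sorted' or 'axis', got {pair_by!r}")
    interval = (later.date - earlier.date).days
    if interval <= 0:
        raise ValueError(
            f"later measurement ({later.date}) must be strictly after earlier ({earlier.date})"
        )
    if interval >= config.growth_window_days:
        return False
    if pair_by == "sorted":
        pairs = _paired_growth(sorted(earlier.dims_mm, reverse=True), sorted(later.dims_mm, reverse=True))
    else:
        pairs = _paired_growth(earlier.dims_mm, later.dims_mm)
    eps = 1e-9
    grown = sum(
        1
        for e, l in pairs
        if (l - e) >= config.growth_fraction * e - eps and (l - e) >= config.growth_min_mm - eps
    )
    return grown >= 2


def diameter_criterion(dims_mm: Sequence[float], config: ScoringConfig | None = None) -> bool:
    """Feature D: largest diameter strictly greater than 3.0 cm (30 mm)."""
    config = config or DEFAULT_CONFIG.scoring
    dims = [float(d) for d in dims_mm]
    if len(dims) != 3:
        raise ValueError(f"exactly three dimensions required, got {len(dims)}")
    if any(d <= 0 for d in dims):
        raise ValueError(f"dimensions must be positive, got {dims}")
    return max(dims) > config.diameter_cutoff_mm
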