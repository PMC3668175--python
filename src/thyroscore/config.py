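"""Versioned configuration: point weights, risk thresholds, statistics and
management options.

The shipped defaults encode the published scoring system (3 / 1 / 0.5 point
feature groups, risk cut-offs at 4 and 7 points).  A YAML file may override
any subset; every override is logged so a scored report can always be traced
back to the rule set that produced it.

Points are handled internally in half-point integer units (``points * 2``)
so the 4.0 and 7.0 category boundaries are exact, never subject to binary
floating-point representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

log = logging.getLogger("thyroscore")

CONFIG_VERSION = 1

#: Default point weights (in points) per feature code.
DEFAULT_WEIGHTS: dict[str, float] = {
    "G": 3.0, "L": 3.0,
    "O": 1.0, "C1": 1.0, "V": 1.0, "E": 1.0,
    "M": 0.5, "H": 0.5, "C2": 0.5, "D": 0.5,
}

#: Risk category boundaries in points: LOW is [0, low_upper), INTERMEDIATE is
#: [low_upper, intermediate_upper), HIGH is [intermediate_upper, inf).
DEFAULT_RISK_BOUNDS: tuple[float, float] = (4.0, 7.0)


def _half_units(points: float, what: str) -> int:
    doubled = points * 2
    if abs(doubled - round(doubled)) > 1e-9:
        raise ValueError(f"{what} must be a multiple of 0.5 points, got {points}")
    return int(round(doubled))


@dataclass(frozen=True)
class ScoringConfig:
    """Weights and risk thresholds for the ultrasound scoring system."""

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    risk_bounds: tuple[float, float] = DEFAULT_RISK_BOUNDS
    #: follow-up window for the rapid-growth rule; 18 months = 548 days
    growth_window_days: int = 548
    growth_fraction: float = 0.20
    growth_min_mm: float = 2.0
    diameter_cutoff_mm: float = 30.0
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        from .features import FEATURE_CODES

        missing = set(FEATURE_CODES) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing for feature(s): {sorted(missing)}")
        for code, w in self.weights.items():
            if w < 0:
                raise ValueError(f"weight for {code} must be non-negative, got {w}")
            _half_units(w, f"weight for {code}")
        lo, hi = self.risk_bounds
        if not 0 < lo < hi:
            raise ValueError(f"risk bounds must satisfy 0 < low < high, got {self.risk_bounds}")
        _half_units(lo, "risk bound")
        _half_units(hi, "risk bound")

    def weight_half_units(self, code: str) -> int:
        return _half_units(self.weights[code], f"weight for {code}")

    @property
    def bounds_half_units(self) -> tuple[int, int]:
        lo, hi = self.risk_bounds
        return _half_units(lo, "bound"), _half_units(hi, "bound")


@dataclass(frozen=True)
class StatsConfig:
    """Options for the 2x2 diagnostic statistics."""

    #: proportion CI method: "clopper-pearson" (exact) or "wilson"
    ci_method: str = "clopper-pearson"
    #: zero-cell odds-ratio policy: "haldane" (add 0.5 to every cell) or "error"
    or_zero_policy: str = "haldane"
    alpha: float = 0.05
    #: integer display convention for report percentages: "truncate" or "round"
    percent_display: str = "truncate"

    def __post_init__(self) -> None:
        if self.ci_method not in ("clopper-pearson", "wilson"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        if self.or_zero_policy not in ("haldane", "error"):
            raise ValueError(f"unknown or_zero_policy {self.or_zero_policy!r}")
        if self.percent_display not in ("truncate", "round"):
            raise ValueError(f"unknown percent_display {self.percent_display!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


_ACTIONS = ("OBSERVE", "REPEAT_FNAB", "SURGERY", "URGENT_SURGERY")

#: Default base action per Bethesda cytology category.  Category IV has a
#: distinct branch when the ultrasound pattern has changed since the biopsy
#: (repeat the biopsy instead of operating on a possibly stale result).
DEFAULT_CYTOLOGY_BASE: dict[str, str] = {
    "I": "REPEAT_FNAB",
    "II": "OBSERVE",
    "III": "REPEAT_FNAB",
    "IV": "SURGERY",
    "IV_US_CHANGED": "REPEAT_FNAB",
    "V": "URGENT_SURGERY",
    "VI": "URGENT_SURGERY",
}

#: Minimum action imposed by the ultrasound risk pattern (benign cytology can
#: be false-negative; a suspicious sonographic pattern escalates management).
DEFAULT_RISK_FLOOR: dict[str, str] = {
    "LOW": "OBSERVE",
    "INTERMEDIATE": "REPEAT_FNAB",
    "HIGH": "SURGERY",
}


@dataclass(frozen=True)
class ManagementConfig:
    """The editable management rule table (see thyroscore.management).

    The recommendation is the more severe of ``cytology_base[category]`` and
    ``risk_floor[us risk]``; intervals attach to OBSERVE / REPEAT_FNAB.
    """

    observe_interval_months: int = 18
    repeat_fnab_interval_months: int = 6
    #: when true, any positive clinical flag upgrades OBSERVE to REPEAT_FNAB
    flags_upgrade_observation: bool = True
    cytology_base: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CYTOLOGY_BASE))
    risk_floor: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RISK_FLOOR))
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.observe_interval_months <= 0 or self.repeat_fnab_interval_months <= 0:
            raise ValueError("follow-up intervals must be positive")
        for table, required in (
            (self.cytology_base, set(DEFAULT_CYTOLOGY_BASE)),
            (self.risk_floor, set(DEFAULT_RISK_FLOOR)),
        ):
            missing = required - set(table)
            if missing:
                raise ValueError(f"rule table missing entries: {sorted(missing)}")
            bad = {a for a in table.values() if a not in _ACTIONS}
            if bad:
                raise ValueError(f"unknown action(s) in rule table: {sorted(bad)}")


@dataclass(frozen=True)
class Config:
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    management: ManagementConfig = field(default_factory=ManagementConfig)


DEFAULT_CONFIG = Config()


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config; absent path returns the shipped defaults.

    Only keys present in the file override defaults; each override is logged.
    """
    if path is None:
        return DEFAULT_CONFIG
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    cfg = DEFAULT_CONFIG
    sections = {"scoring": cfg.scoring, "stats": cfg.stats, "management": cfg.management}
    new = {}
    for name, section in sections.items():
        overrides = raw.get(name, {}) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        unknown = set(overrides) - {f.name for f in section.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ValueError(f"unknown key(s) in config section {name!r}: {sorted(unknown)}")
        for key, value in overrides.items():
            log.info("config override: %s.%s = %r", name, key, value)
        if "risk_bounds" in overrides:
            overrides["risk_bounds"] = tuple(overrides["risk_bounds"])
        new[name] = replace(section, **overrides) if overrides else section
    return Config(**new)


def dump_default_config(path: str | Path) -> None:
    """Write the shipped default configuration as editable YAML."""
    cfg = DEFAULT_CONFIG
    data = {
        "scoring": {
            "weights": cfg.scoring.weights,
            "risk_bounds": list(cfg.scoring.risk_bounds),
            "growth_window_days": cfg.scoring.growth_window_days,
            "growth_fraction": cfg.scoring.growth_fraction,
            "growth_min_mm": cfg.scoring.growth_min_mm,
            "diameter_cutoff_mm": cfg.scoring.diameter_cutoff_mm,
        },
        "stats": {
            "ci_method": cfg.stats.ci_method,
            "or_zero_policy": cfg.stats.or_zero_policy,
            "alpha": cfg.stats.alpha,
            "percent_display": cfg.stats.percent_display,
        },
        "management": {
            "observe_interval_months": cfg.management.observe_interval_months,
            "repeat_fnab_interval_months": cfg.management.repeat_fnab_interval_months,
            "flags_upgrade_observation": cfg.management.flags_upgrade_observation,
            "cytology_base": cfg.management.cytology_base,
            "risk_floor": cfg.management.risk_floor,
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
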