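"""Diagnostic-performance statistics on 2x2 feature-by-histology tables.

For each ultrasound characteristic the cohort is cross-tabulated as

====================  ==========  ========
..                    malignant   benign
feature positive      tp          fp
feature negative      fn          tn
====================  ==========  ========

from which sensitivity, specificity, PPV and NPV (with exact Clopper-Pearson
95% binomial intervals by default), the cross-product odds ratio with a
Woolf log-normal interval, and a two-sided Fisher exact p-value are derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .config import DEFAULT_CONFIG, StatsConfig
from .features import EVALUATED_FEATURES, USFeatureProfile

log = logging.getLogger("thyroscore")

__all__ = [
    "ContingencyTable",
    "ProportionEstimate",
    "OddsRatioEstimate",
    "DiagnosticMetrics",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "odds_ratio",
    "fisher_exact",
    "compute_metrics",
    "feature_performance_table",
    "tabulate_feature",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for this table."""


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2x2 counts: feature-positive/negative by malignant/benign."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        """Rows = feature positive/negative, columns = malignant/benign."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])

    def swap_rows(self) -> "ContingencyTable":
        return ContingencyTable(tp=self.fn, fn=self.tp, fp=self.tn, tn=self.fp)


@dataclass(frozen=True, slots=True)
class ProportionEstimate:
    """A proportion in percent with its confidence interval."""

    percent: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    def display_int(self, convention: str = "truncate") -> int:
        """Integer percent for report output.

        ``truncate`` floors toward zero (the convention the shipped
        reference tables follow); ``round`` is round-half-up.
        """
        if convention == "truncate":
            return int(self.percent)
        if convention == "round":
            return int(math.floor(self.percent + 0.5))
        raise ValueError(f"unknown display convention {convention!r}")


@dataclass(frozen=True, slots=True)
class OddsRatioEstimate:
    value: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 correction applied


@dataclass(frozen=True, slots=True)
class DiagnosticMetrics:
    """Per-feature metrics; a proportion is ``None`` when its margin is empty
    (e.g. PPV in a cohort where no record is feature-positive)."""

    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None
    ppv: ProportionEstimate | None
    npv: ProportionEstimate | None
    odds_ratio: OddsRatioEstimate
    fisher_p: float


def _proportion(num: int, den: int, metric: str, config: StatsConfig) -> ProportionEstimate:
    if den == 0:
        raise UndefinedMetricError(f"{metric} undefined: denominator is zero")
    method = {"clopper-pearson": "beta", "wilson": "wilson"}[config.ci_method]
    lo, hi = proportion_confint(num, den, alpha=config.alpha, method=method)
    return ProportionEstimate(
        percent=100.0 * num / den,
        ci_low=100.0 * float(lo),
        ci_high=100.0 * float(hi),
        numerator=num,
        denominator=den,
    )


def sensitivity(table: ContingencyTable, config: StatsConfig | None = None) -> ProportionEstimate:
    """tp / (tp + fn), in percent, with binomial CI."""
    return _proportion(table.tp, table.tp + table.fn, "sensitivity", config or DEFAULT_CONFIG.stats)


def specificity(table: ContingencyTable, config: StatsConfig | None = None) -> ProportionEstimate:
    """tn / (fp + tn), in percent, with binomial CI."""
    return _proportion(table.tn, table.fp + table.tn, "specificity", config or DEFAULT_CONFIG.stats)


def ppv(table: ContingencyTable, config: StatsConfig | None = None) -> ProportionEstimate:
    """tp / (tp + fp), in percent, with binomial CI."""
    return _proportion(table.tp, table.tp + table.fp, "PPV", config or DEFAULT_CONFIG.stats)


def npv(table: ContingencyTable, config: StatsConfig | None = None) -> ProportionEstimate:
    """tn / (fn + tn), in percent, with binomial CI."""
    return _proportion(table.tn, table.fn + table.tn, "NPV", config or DEFAULT_CONFIG.stats)


def odds_ratio(table: ContingencyTable, config: StatsConfig | None = None) -> OddsRatioEstimate:
    """Cross-product odds ratio (tp*tn)/(fn*fp) with a Woolf 95% CI.

    A zero cell triggers the configured policy: Haldane-Anscombe 0.5
    continuity correction of every cell (default, logged) or an error.
    """
    config = config or DEFAULT_CONFIG.stats
    cells = np.array([table.tp, table.fn, table.fp, table.tn], dtype=float)
    corrected = False
    if np.any(cells == 0):
        if config.or_zero_policy == "error":
            raise UndefinedMetricError("odds ratio undefined: zero cell in table")
        log.warning("zero cell in 2x2 table; applying Haldane-Anscombe 0.5 correction")
        cells = cells + 0.5
        corrected = True
    a, b, c, d = cells
    value = (a * d) / (b * c)
    z = sps.norm.ppf(1 - config.alpha / 2)
    se = math.sqrt((1 / cells).sum())
    return OddsRatioEstimate(
        value=value,
        ci_low=math.exp(math.log(value) - z * se),
        ci_high=math.exp(math.log(value) + z * se),
        corrected=corrected,
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood convention)."""
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided").pvalue)


def compute_metrics(table: ContingencyTable, config: StatsConfig | None = None) -> DiagnosticMetrics:
    """All diagnostic metrics for one 2x2 table.

    Unlike the individual metric functions, which raise on an empty margin,
    this bundles a ``None`` for any undefined proportion so a whole cohort
    report never fails on one degenerate feature.
    """
    config = config or DEFAULT_CONFIG.stats

    def safe(metric):
        try:
            return metric(table, config)
        except UndefinedMetricError:
            return None

    return DiagnosticMetrics(
        sensitivity=safe(sensitivity),
        specificity=safe(specificity),
        ppv=safe(ppv),
        npv=safe(npv),
        odds_ratio=odds_ratio(table, config),
        fisher_p=fisher_exact(table),
    )


def tabulate_feature(
    cohort: Iterable[tuple[USFeatureProfile, bool]], code: str
) -> ContingencyTable:
    """Cross-tabulate one feature against the malignancy label."""
    tp = fn = fp = tn = 0
    for profile, malignant in cohort:
        positive = profile.code_values()[code]
        if malignant:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)


def feature_performance_table(
    cohort: Sequence[tuple[USFeatureProfile, bool]],
    features: Sequence[str] = EVALUATED_FEATURES,
    config: StatsConfig | None = None,
) -> dict[str, DiagnosticMetrics]:
    """Per-feature diagnostic metrics over a labelled cohort.

    The default feature set and ordering are the seven statistically
    evaluated characteristics (V, C1, O, C2, E, M, H).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    labels = {bool(m) for _, m in cohort}
    if labels != {True, False}:
        raise ValueError("cohort must contain both malignant and benign records")
    config = config or DEFAULT_CONFIG.stats
    # one pass over the cohort builds every table (cohorts can be large)
    mal = np.array([bool(m) for _, m in cohort])
    matrix = np.array(
        [[v for v in p.code_values().values()] for p, _ in cohort], dtype=bool
    )
    from .features import FEATURE_CODES

    col = {c: i for i, c in enumerate(FEATURE_CODES)}
    out: dict[str, DiagnosticMetrics] = {}
    for code in features:
        pos = matrix[:, col[code]]
        table = ContingencyTable(
            tp=int((pos & mal).sum()),
            fn=int((~pos & mal).sum()),
            fp=int((pos & ~mal).sum()),
            tn=int((~pos & ~mal).sum()),
        )
        out[code] = compute_metrics(table, config)
    return out
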