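"""Report rendering: feature-distribution and diagnostic-performance tables.

Two table styles are produced from a labelled cohort:

* a distribution table — per-feature 2x2 counts with the Fisher exact
  p-value for the malignant/benign contrast;
* a performance table — sensitivity, specificity, PPV and NPV as integer
  percentages with 95% CIs (``"96 (90-99)"``), plus the odds ratio to two
  decimals.

Both are available as DataFrames (for CSV export) and as aligned text.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, StatsConfig
from .features import EVALUATED_FEATURES, FEATURE_NAMES, USFeatureProfile
from .stats import (
    ContingencyTable,
    DiagnosticMetrics,
    ProportionEstimate,
    feature_performance_table,
    fisher_exact,
    tabulate_feature,
)

__all__ = [
    "distribution_frame",
    "performance_frame",
    "render_text",
    "format_percent_ci",
]


def format_percent_ci(est: ProportionEstimate | None, convention: str = "truncate") -> str:
    """``"96 (90-99)"``: integer point estimate with integer CI bounds.

    CI bounds are rounded to the nearest integer; the point estimate follows
    the configured display convention.  An undefined metric renders as "n/a".
    """
    if est is None:
        return "n/a"
    lo = int(round(est.ci_low))
    hi = int(round(est.ci_high))
    return f"{est.display_int(convention)} ({lo}-{hi})"


def _format_p(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


def distribution_frame(
    cohort: Sequence[tuple[USFeatureProfile, bool]],
    features: Sequence[str] = EVALUATED_FEATURES,
) -> pd.DataFrame:
    """Per-feature counts in malignant and benign lesions, with Fisher p."""
    rows = []
    for code in features:
        t: ContingencyTable = tabulate_feature(cohort, code)
        rows.append(
            {
                "feature": code,
                "parameter": FEATURE_NAMES[code],
                "positive_malignant": t.tp,
                "negative_malignant": t.fn,
                "positive_benign": t.fp,
                "negative_benign": t.tn,
                "p_value": _format_p(fisher_exact(t)),
            }
        )
    return pd.DataFrame(rows)


def performance_frame(
    metrics: Mapping[str, DiagnosticMetrics] | None = None,
    cohort: Sequence[tuple[USFeatureProfile, bool]] | None = None,
    features: Sequence[str] = EVALUATED_FEATURES,
    config: StatsConfig | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV (integer % with CI) and odds ratio."""
    config = config or DEFAULT_CONFIG.stats
    if metrics is None:
        if cohort is None:
            raise ValueError("either metrics or cohort must be given")
        metrics = feature_performance_table(cohort, features, config)
    conv = config.percent_display
    rows = []
    for code in features:
        m = metrics[code]
        rows.append(
            {
                "feature": code,
                "parameter": FEATURE_NAMES[code],
                "sensitivity_pct": format_percent_ci(m.sensitivity, conv),
                "specificity_pct": format_percent_ci(m.specificity, conv),
                "ppv_pct": format_percent_ci(m.ppv, conv),
                "npv_pct": format_percent_ci(m.npv, conv),
                "odds_ratio": f"{m.odds_ratio.value:.2f}",
                "fisher_p": _format_p(m.fisher_p),
            }
        )
    return pd.DataFrame(rows)


def render_text(frame: pd.DataFrame, title: str | None = None) -> str:
    """Aligned plain-text rendering of a report frame."""
    body = frame.to_string(index=False)
    return f"{title}\n{'=' * len(title)}\n{body}\n" if title else body + "\n"
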