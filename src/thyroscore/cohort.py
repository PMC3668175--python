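"""Synthetic nodule cohorts with class-conditional feature prevalences.

Real per-nodule data behind published diagnostic tables are almost never
released; what is published are marginal 2x2 counts.  This module generates
record-level cohorts that are consistent with such marginals, either by
Bernoulli sampling (``simulate_cohort``) or by deterministic quota filling
(``exact_cohort_from_counts``), so scoring and diagnostic statistics can be
exercised end to end without clinical data.

Features are sampled independently within each class: only marginal
prevalences are published, so no correlation structure is assumed.  All
marginal statistics (sensitivity, specificity, PPV, NPV, odds ratios) are
invariant to that choice; joint-feature quantities (such as the
distribution of total scores) are not, and should not be read off these
cohorts as estimates of clinical reality.  ``correlate`` accepts a
user-supplied post-processing hook for experimenting with dependence;
nothing ships enabled.

Default prevalences are the development-cohort proportions
(:data:`thyroscore.reference.STUDY_PREVALENCES`): e.g. abnormal vascularity
0.96 in malignant vs 0.54 in benign lesions; rapid growth, pathologic lymph
nodes and diameter > 3 cm at zero prevalence, as in the development cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .features import FEATURE_CODES, FEATURE_FIELDS, USFeatureProfile
from .reference import STUDY_PREVALENCES
from .stats import ContingencyTable

__all__ = ["CohortSpec", "simulate_cohort", "exact_cohort_from_counts"]

Cohort = list[tuple[USFeatureProfile, bool]]


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort.

    ``feature_prevalence`` maps feature code to
    ``(P(feature | malignant), P(feature | benign))``; unspecified features
    fall back to the development-cohort defaults.
    """

    n_malignant: int = 100
    n_benign: int = 100
    feature_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(STUDY_PREVALENCES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 0 or self.n_benign < 0:
            raise ValueError("cohort sizes must be non-negative")
        unknown = set(self.feature_prevalence) - set(FEATURE_CODES)
        if unknown:
            raise ValueError(f"unknown feature code(s): {sorted(unknown)}")
        for code, (p_mal, p_ben) in self.feature_prevalence.items():
            if not (0.0 <= p_mal <= 1.0 and 0.0 <= p_ben <= 1.0):
                raise ValueError(
                    f"prevalences for {code} must lie in [0, 1], got ({p_mal}, {p_ben})"
                )

    def prevalence(self, code: str) -> tuple[float, float]:
        return self.feature_prevalence.get(code, STUDY_PREVALENCES.get(code, (0.0, 0.0)))


def _profiles_from_matrix(matrix: np.ndarray) -> list[USFeatureProfile]:
    fields = [FEATURE_FIELDS[c] for c in FEATURE_CODES]
    return [
        USFeatureProfile(**{f: bool(v) for f, v in zip(fields, row)}) for row in matrix
    ]


def simulate_cohort(
    spec: CohortSpec,
    correlate: Callable[[np.ndarray, bool, np.random.Generator], np.ndarray] | None = None,
) -> Cohort:
    """Draw a cohort with independent per-feature Bernoulli features.

    Reproducible for a fixed ``spec.seed``.  Malignant records come first.
    ``correlate``, if given, may rewrite the boolean feature matrix of each
    class (rows = records, columns = features in canonical order) to inject
    dependence; it must preserve the matrix shape.
    """
    rng = np.random.default_rng(spec.seed)
    cohort: Cohort = []
    for malignant, n in ((True, spec.n_malignant), (False, spec.n_benign)):
        probs = np.array([spec.prevalence(c)[0 if malignant else 1] for c in FEATURE_CODES])
        matrix = rng.random((n, len(FEATURE_CODES))) < probs
        if correlate is not None:
            matrix = correlate(matrix, malignant, rng)
            if matrix.shape != (n, len(FEATURE_CODES)):
                raise ValueError("correlate hook must preserve the matrix shape")
        cohort.extend((p, malignant) for p in _profiles_from_matrix(matrix))
    return cohort


def exact_cohort_from_counts(tables: dict[str, ContingencyTable]) -> Cohort:
    """Deterministic cohort whose per-feature 2x2 tables equal ``tables``.

    Each feature is assigned independently per class by filling quotas in
    record order (the first ``tp`` malignant records are feature-positive,
    and so on); the joint distribution of features is not constrained and
    carries no meaning.  Features not listed are false everywhere.
    """
    if not tables:
        raise ValueError("at least one feature table required")
    unknown = set(tables) - set(FEATURE_CODES)
    if unknown:
        raise ValueError(f"unknown feature code(s): {sorted(unknown)}")
    n_mal = {c: t.tp + t.fn for c, t in tables.items()}
    n_ben = {c: t.fp + t.tn for c, t in tables.items()}
    if len(set(n_mal.values())) != 1 or len(set(n_ben.values())) != 1:
        raise ValueError(
            f"inconsistent class totals across features: malignant {n_mal}, benign {n_ben}"
        )
    n_malignant = next(iter(n_mal.values()))
    n_benign = next(iter(n_ben.values()))

    def build(n: int, positives: dict[str, int]) -> np.ndarray:
        matrix = np.zeros((n, len(FEATURE_CODES)), dtype=bool)
        for j, code in enumerate(FEATURE_CODES):
            matrix[: positives.get(code, 0), j] = True
        return matrix

    mal = build(n_malignant, {c: t.tp for c, t in tables.items()})
    ben = build(n_benign, {c: t.fp for c, t in tables.items()})
    return [(p, True) for p in _profiles_from_matrix(mal)] + [
        (p, False) for p in _profiles_from_matrix(ben)
    ]
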