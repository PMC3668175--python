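# Methods

## The scoring model

The score is a linear point system over ten binary ultrasound
characteristics of a thyroid nodule or focal lesion. Weights encode three
tiers of prognostic importance: the strongest clinical alarm signs — rapid
growth (G) and pathologically altered cervical lymph nodes (L) — carry 3
points each; the four sonographic features with the strongest measured
association with malignancy — taller-than-wide orientation (O),
microcalcifications (C1), abnormal vascularity (V), hypoechogenicity (E) —
carry 1 point; minor predictors — irregular margin (M), absent/irregular
halo (H), solid composition (C2), diameter > 3 cm (D) — carry 0.5 points.
The total (0–12) stratifies the US pattern into LOW (< 4), INTERMEDIATE
(4 ≤ S < 7) and HIGH (≥ 7) risk of malignancy.

All score arithmetic runs in half-point integer units (`2·S` as an `int`),
so the category boundaries at 4.0 and 7.0 are exact and immune to binary
floating-point representation. The LOW band is implemented as
`0 ≤ S < 4`: a zero score must classify, and negative scores are
impossible by construction. Weights and thresholds ship as a versioned
configuration (`thyroscore.config`); overrides are validated (half-point
multiples, ordered positive bounds) and logged.

### Derived features

* **Rapid growth (G).** Two dated measurements of three orthogonal
  dimensions (mm) establish G when the interval is *strictly* shorter than
  18 months — implemented as 548 days (365.25 × 1.5, rounded) — and at
  least two of three paired dimensions each grew by ≥ 20% of the earlier
  value *and* by ≥ 2 mm absolutely. Both growth comparisons use a 1 ns-scale
  epsilon so exact-boundary cases (e.g. 10 → 12 mm) count as met. Serial
  scans rarely preserve axis identity, so dimensions are paired
  largest-to-largest by default; axis-wise pairing is available when the
  acquisition guarantees axis labels. Reversed or zero-length intervals are
  errors, not `False`.
* **Diameter (D).** Strictly greater than 30.0 mm on the largest dimension.
  The strict inequality follows the defining wording of the weight table
  ("longer than 3.0 cm"); discussions of 3–4 cm lesions elsewhere in the
  source literature are not used.

### Missingness

Scoring requires a complete profile; `USFeatureProfile` rejects anything
that is not an explicit boolean. The CSV layer resolves missing cells by
policy: `reject` (default) fails the record with its line number; `false`
imputes absence with a logged warning. Silent imputation would change
scores invisibly, so there is no quiet default. D and G are derived from
dimension/date columns when their cells are blank but the measurements are
present.

## Diagnostic statistics

Each feature is cross-tabulated against histological truth as a 2×2 table
(tp = feature-positive malignant, etc.). Proportion metrics are
`100·tp/(tp+fn)` (sensitivity), `100·tn/(fp+tn)` (specificity),
`100·tp/(tp+fp)` (PPV), `100·tn/(fn+tn)` (NPV). The 95% intervals are
exact Clopper–Pearson by default (via `statsmodels`), chosen because the
reference performance table's printed integer intervals are consistent
with the exact method after rounding; Wilson is available by
configuration. The odds ratio is the cross-product ratio with a Woolf
log-normal interval, `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`. A zero cell
triggers, by configurable policy, either the Haldane–Anscombe correction
(add 0.5 to every cell; default, logged) or an undefined-OR error. The
Fisher exact test is two-sided by the minimum-likelihood convention
(`scipy.stats.fisher_exact`); the test suite cross-checks it against
brute-force enumeration of all same-margin tables.

Individual metric functions raise a named error on an empty margin;
the batch table builder instead records the metric as undefined (`n/a` in
reports) so one degenerate feature cannot sink a cohort report.

### Display rounding

Reports print proportions as integer percent. The shipped reference
tables were evidently produced with a mixed rounding convention: 26 of
their 28 point-estimate cells equal the value truncated toward zero, the
other two equal round-half-up, and their CI bounds mix the same two rules.
The package defaults to truncation (the best single-rule match) and keeps
full precision internally; the two cells that only reproduce under the
other rule are knowingly asserted as printed — and fail — in the
acceptance tests rather than being special-cased.

## Management engine

Two independent readings are combined. Cytology fixes a base action:
TBSRTC V/VI → urgent referral for surgery; IV → surgery, with a repeat
biopsy instead only when the US pattern has changed since the aspirate
(a repeat is otherwise futile for a confirmed follicular-neoplasm
diagnosis); III and I → repeat biopsy; II → observation. The US risk
pattern imposes a floor — LOW: observe, INTERMEDIATE: repeat biopsy,
HIGH: surgery — motivated by the up-to-3% false-negative rate of benign
cytology and by the position that a sufficiently suspicious sonographic
pattern can ground the therapeutic decision itself. The recommendation is
the more severe of base and floor (severity OBSERVE < REPEAT_FNAB <
SURGERY < URGENT_SURGERY).

This max-composition is the package's own reconstruction: the source
algorithm's exact branch diagram is not recoverable from its textual
description, which pins down only the cytology rules and the
benign-cytology escalations. Composition by maximum is the unique minimal
rule that honours every pinned-down cell while keeping action severity
monotone both in cytology rank (II < I ≈ III < IV < V ≤ VI) and in US
risk — a safety property a clinical cascade should not violate. The whole
table ships as editable YAML (`cytology_base`, `risk_floor`) and must not
be presented as the verbatim published algorithm.

Clinical flags (age < 20 or > 60, male sex, neck/head irradiation, family
history, alarm symptoms such as non-laryngeal hoarseness, tumour ache,
dysphagia) are advisory: they annotate the audit trail and, by default,
upgrade plain observation to a repeat biopsy; they never downgrade.
Intervals: observation re-biopsies after 18 months (the worked low-risk
case); repeat biopsies default to 6 months, a conventional interval for
indeterminate or nondiagnostic aspirates — the source states none, so it
is a package default, editable in config. The urgent/ordinary surgery
distinction applies to cytology V/VI only; operability exceptions are out
of scope.

## Synthetic cohorts

`simulate_cohort` draws each feature independently within class from
Bernoulli distributions with class-conditional prevalences; the defaults
are the development cohort's empirical proportions (e.g. V: 0.96
malignant / 0.54 benign), with G, L and D at zero prevalence because that
cohort contained no scorable growth observations, no lymph-node feature
outside malignant foci, and no lesion over 3 cm. Only marginal tables are
published, so no dependence structure is assumed. Consequences:

* every *marginal* statistic (sensitivity, specificity, PPV, NPV, OR,
  Fisher p) is faithful and is what the tests check;
* *joint* quantities — notably the distribution of total scores and hence
  the mix of risk categories — are **not** calibrated to reality, because
  suspicious features co-occur in real nodules far more than independence
  implies. Passing tests therefore validate the computational pipeline,
  not the clinical case mix. A `correlate` hook accepts a user-supplied
  rewrite of the per-class feature matrix for dependence experiments;
  nothing ships enabled.

`exact_cohort_from_counts` builds a deterministic cohort reproducing given
per-feature 2×2 counts exactly by quota-filling in record order; its joint
distribution is an artifact and carries no meaning.

## Numerical and testing choices

* Scores: exact half-unit integer arithmetic; no tolerance needed.
* Growth/diameter comparisons: 1e-9 epsilon on the ≥ comparisons.
* Reproducibility: all simulation flows through
  `numpy.random.default_rng(seed)`; identical spec + seed gives
  byte-identical cohort files. Hypothesis-based property tests run
  derandomised.
* Problem sizes: coverage of the exact binomial interval is checked with
  10⁴ simulated samples at n = 100, p = 0.64 (tolerance 1 point below the
  nominal 95%); prevalence recovery uses a 10⁵-record cohort (5·10⁴ per
  class) with a 3-Monte-Carlo-SE band, and the convergence unit test uses
  10⁵ records per class with an absolute 0.01 band. These sizes make the
  stochastic checks sharp while keeping the default suite fast.
* The Fisher brute-force oracle enumerates the hypergeometric support
  directly for tables with n ≤ ~30; the empty table is defined as p = 1.

## Limitations

* Feature booleans are trusted inputs; inter-observer variability of US
  reading, the dominant error source in practice, is out of scope.
* The development data's equal 100/100 class design does not reflect
  clinical prevalence; PPV/NPV computed from it are design-conditional,
  and the package makes no prevalence adjustment.
* The management table is a reconstruction (above) and advisory only.
* Independence of simulated features limits synthetic cohorts to
  marginal-statistic validation.
* No ROC analysis, multivariable modelling, or multiplicity correction is
  provided, matching the univariate design the statistics reproduce.
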