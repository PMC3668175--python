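# thyroscore

Risk stratification and management support for thyroid nodules and focal
lesions, combining an ultrasound (US) feature score with fine-needle
aspiration biopsy (FNAB) cytology reported in the Bethesda system (TBSRTC).

Thyroid US detects far more lesions than palpation, and most are benign;
the clinical question is which nodules to observe, re-biopsy, or operate
on. `thyroscore` is for endocrinologists, sonographers and biostatisticians
who want a transparent, auditable implementation of a published-style point
score over sonographic malignancy predictors, the diagnostic-performance
statistics behind it, and the decision rules that combine the US pattern
with cytology.

## The score

Ten binary characteristics, each with a letter code and a weight:

| Points | Features |
|---|---|
| 3 | **G** rapid growth (≥20% in ≥2 dimensions, ≥2 mm, within <18 months); **L** pathologically altered cervical lymph nodes |
| 1 | **O** taller-than-wide orientation; **C1** microcalcifications; **V** abnormal vascularity (increased intranodular, or absent flow in a hypoechoic solid lesion); **E** hypoechogenicity |
| 0.5 | **M** irregular margin; **H** absent or irregular halo; **C2** solid composition; **D** diameter > 3.0 cm |

The total `S = Σ wᵢ·xᵢ` (0 ≤ S ≤ 12, half-point steps) maps to a US risk
pattern: **LOW** for 0 ≤ S < 4, **INTERMEDIATE** for 4 ≤ S < 7, **HIGH**
for S ≥ 7.

Each feature's association with histologically confirmed malignancy is
quantified on 2×2 tables by sensitivity, specificity, PPV and NPV with
exact Clopper–Pearson 95% intervals, the cross-product odds ratio
`OR = (tp·tn)/(fn·fp)` with a Woolf log-normal interval, and a two-sided
Fisher exact test. A management engine combines the US risk pattern with
the TBSRTC category (I–VI) and advisory clinical flags into one of
OBSERVE / REPEAT_FNAB / SURGERY / URGENT_SURGERY with a fired-rule audit
trail. A synthetic-cohort simulator (per-feature Bernoulli, class-conditional
prevalences) makes the whole pipeline testable end to end.

## Worked example

Three cases spanning the risk categories, as a cohort CSV:

```csv
id,G,L,O,C1,V,E,M,H,C2,D,tbsrtc
fig2,0,0,0,0,0,1,0,0,1,0,II
fig3,0,0,1,1,1,1,1,1,1,0,IV
fig4,0,1,0,1,1,1,1,1,1,0,V
```

```text
$ thyroscore score nodules.csv
id,points_G,points_L,points_O,points_C1,points_V,points_E,points_M,points_H,points_C2,points_D,total,risk
fig2,0.0,0.0,0.0,0.0,0.0,1.0,0.0,0.0,0.5,0.0,1.5,LOW
fig3,0.0,0.0,1.0,1.0,1.0,1.0,0.5,0.5,0.5,0.0,5.5,INTERMEDIATE
fig4,0.0,3.0,0.0,1.0,1.0,1.0,0.5,0.5,0.5,0.0,7.5,HIGH
```

The hypoechoic solid nodule (`fig2`) scores 1.5 points — a low-risk US
pattern; with benign cytology (TBSRTC II) the engine recommends observation
with a repeat FNAB after 18 months. The 5.5-point intermediate-risk lesion
with a follicular-neoplasm aspirate (IV) and the 7.5-point high-risk lesion
(a metastatic node alone contributes 3 points) with suspicious cytology (V)
both go to surgery, the latter urgently:

```text
$ thyroscore recommend nodules.csv
[
  {"id": "fig2", "total_score": 1.5, "us_risk": "LOW", "tbsrtc": "II",
   "action": "OBSERVE", "repeat_interval_months": 18, "rationale": ["CYT_II"]},
  {"id": "fig3", "total_score": 5.5, "us_risk": "INTERMEDIATE", "tbsrtc": "IV",
   "action": "SURGERY", "repeat_interval_months": null, "rationale": ["CYT_IV"]},
  {"id": "fig4", "total_score": 7.5, "us_risk": "HIGH", "tbsrtc": "V",
   "action": "URGENT_SURGERY", "repeat_interval_months": null, "rationale": ["CYT_V"]}
]
```

Diagnostic performance on a labelled cohort (here the deterministic cohort
reconstructed from the development study's 2×2 counts, 100 malignant + 100
benign lesions):

```text
$ thyroscore report cohort.csv
Diagnostic performance
======================
feature                          parameter sensitivity_pct specificity_pct     ppv_pct    npv_pct odds_ratio fisher_p
      V  Vascularity (intranodular/absent)      96 (90-99)      46 (36-56)  64 (56-72) 92 (81-98)      20.44  <0.0001
     C1                Microcalcifications      93 (86-97)      65 (55-74)  72 (64-80) 90 (81-96)      24.67  <0.0001
      O     Orientation (taller-than-wide)      86 (78-92)     98 (93-100) 97 (92-100) 87 (80-93)     301.00  <0.0001
     C2                Composition (solid)      94 (87-98)      21 (13-30)  54 (47-62) 77 (58-91)       4.16   0.0032
      E       Echogenicity (hypoechogenic)      84 (75-91)      78 (69-86)  79 (70-87) 82 (74-90)      18.61  <0.0001
      M                Margins (irregular)      77 (68-85)      70 (60-79)  71 (62-80) 75 (65-84)       7.81  <0.0001
      H Peripheral halo (absent/irregular)      76 (66-84)      65 (55-74)  68 (59-77) 73 (63-82)       5.88  <0.0001
```

Taller-than-wide orientation is the strongest single predictor (OR 301,
specificity 98%); solid composition is sensitive (94%) but nearly
unspecific (21%) — no single feature separates benign from malignant, which
is why the score aggregates them. `thyroscore simulate` draws synthetic
cohorts with configurable class-conditional prevalences, and
`thyroscore evaluate` writes the same tables as CSV.

## Scope

Feature booleans are inputs: the package does no image analysis, and the
rule engine is decision *support* — it encodes one published-style
algorithm reconstruction (editable as YAML config) and is not a substitute
for clinical judgement. See `docs/methods.md` for the model's assumptions
and known limitations.
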