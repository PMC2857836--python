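# homacut

Optimal HOMA-IR diagnostic cut-points for metabolic syndrome from
cross-sectional survey data.

## The problem

The homeostasis model assessment of insulin resistance,

    HOMA-IR = I0 [µU/mL] x G0 [mg/dL] / 405,

is the standard fasting-sample surrogate for insulin resistance in
epidemiological studies, but its diagnostic cut-off is population-specific
and has to be re-derived for each cohort. `homacut` implements the full
survey workflow for doing so: ingesting raw clinical records, excluding
pregnant women and records with incomplete labs, deriving BMI, Friedewald
LDL and HOMA-IR, classifying metabolic syndrome (MetS) under the ATPIII
rule (any 3 of 5 components: waist ≥ 102/88 cm for men/women, TG ≥ 150
mg/dL, HDL < 40/50 mg/dL, BP ≥ 130/85 mmHg or antihypertensive medication,
FPG ≥ 100 mg/dL or diabetes) and the IDF rule (mandatory central obesity,
waist > 90 cm, plus any 2 of the remaining 4), post-stratifying to census
age-decade x sex population shares, and selecting cut-offs from the
weighted empirical ROC curve of HOMA-IR against the MetS label.

Two selection criteria are provided, with the positivity rule
score ≥ threshold:

* **Youden index** `J = Se + Sp − 1`, maximized (the `1 + J` scale some
  reports print is reported alongside);
* **distance to the perfect corner** `d² = (1 − Se)² + (1 − Sp)²`,
  minimized.

The package also produces percentile threshold tables (50th–95th), positive
likelihood ratio curves `PLR = Se / (1 − Sp)`, trapezoidal AUC with a seeded
percentile-bootstrap 95% CI, and weighted cohort summaries (mean ± SEM,
prevalence, Pearson correlation). Analyses run separately in the
nondiabetic and diabetic strata (diabetes = interview history or
FPG ≥ 126 mg/dL by default) and for metabolically normal subjects.

Because the underlying national survey microdata are not publicly
deposited, the package ships a synthetic cohort generator
(`homacut.synthetic_survey`) whose subjects are driven by a single latent
insulin-resistance factor: it reproduces the study's qualitative structure
(correlated cardiometabolic variables, ~12% diabetic subjects, MetS
prevalence near one third, HOMA-IR AUC in the 0.6–0.7 band, far higher
optimal cut-offs in diabetics) with known ground truth, so every pipeline
stage is testable end to end.

## Worked example

```python
from homacut import (GeneratorConfig, generate_cohort, apply_exclusions,
                     derive_measures, assess_cohort, poststratification_weights,
                     empirical_roc, auc, optimal_cutpoint)

cohort = generate_cohort(GeneratorConfig(seed=20070))        # 4,233 raw records
analyzed, excluded = apply_exclusions(cohort)
analyzed = derive_measures(analyzed)                         # adds bmi, ldl, homa_ir
assessment = assess_cohort(analyzed)                         # MetS flags + stratum
weights = poststratification_weights(analyzed)               # census age x sex

nondiab = (assessment["stratum"] == "nondiabetic").to_numpy()
roc = empirical_roc(
    analyzed["homa_ir"].to_numpy()[nondiab],
    assessment["mets_atpiii"].to_numpy()[nondiab],
    weights[nondiab],
)
cut = optimal_cutpoint(roc, method="youden")
print(f"analyzed {len(analyzed)} of {len(cohort)} records "
      f"({len(excluded)} excluded)")
print(f"ATPIII MetS, nondiabetic stratum: AUC = {auc(roc):.3f}")
print(f"optimal HOMA-IR cut-off (Youden) = {cut.threshold:.3f} "
      f"(sens {cut.sensitivity:.1%}, spec {cut.specificity:.1%}, "
      f"J = {cut.youden_j:.3f}, PLR = {cut.plr:.2f})")
```

prints

```
analyzed 3117 of 4233 records (1116 excluded)
ATPIII MetS, nondiabetic stratum: AUC = 0.698
optimal HOMA-IR cut-off (Youden) = 1.795 (sens 73.3%, spec 58.7%, J = 0.320, PLR = 1.78)
```

i.e. on this synthetic draw roughly a quarter of records are excluded for
pregnancy or missing labs, HOMA-IR discriminates ATPIII-defined MetS with
AUC ≈ 0.70 among nondiabetics, and the Youden-optimal cut-off lands near
1.8 — the neighborhood reported for Middle Eastern adult populations. The
same analysis in the diabetic stratum yields cut-offs around 4.

## Command line

```bash
homacut generate --n 4233 --seed 20070 --out cohort.csv
homacut classify --input cohort.csv --out assessment.csv
homacut cutpoint --input cohort.csv --stratum diabetic --criteria idf --method distance
homacut report   --input cohort.csv --out-dir results/
homacut all      --out-dir results/          # synthetic preset end to end
```

`report`/`all` write the full bundle: analyzed cohort and exclusion log,
per-subject assessment, weighted characteristics table, percentile/PLR
tables and criterion-vs-threshold curves per definition x stratum,
`cutpoints.csv`, `summary.json` and a run `manifest.json`. All output is
delimited text or JSON; a rerun with the same seed is byte-identical. Exit
codes: 0 success, 1 user error (missing/invalid files), 2 data error.

Input cohort files are comma- (or tab-) delimited with a header row; the
canonical columns are `subject_id, age, sex, weight, height, waist, sbp,
dbp, fpg, insulin, tg, hdl, tc, ldl_direct, diabetes_history,
antihypertensive_med, pregnant` (units documented in
`homacut.clinical_records`; missing values empty or `NA`). A custom census
table (`age_band, sex, proportion`) can be supplied with `--census`; a
custom generator configuration as JSON with `generate --config`.

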