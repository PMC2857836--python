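# Methods

## Analysis model

The pipeline estimates population-referenced diagnostic cut-offs of
HOMA-IR (fasting insulin in µU/mL times fasting glucose in mg/dL, divided
by 405; insulin in µU/mL is numerically identical to mU/L, the scale the
405 constant assumes) for metabolic syndrome in a cross-sectional survey
of adults aged 25–64.

**Exclusions.** Records are dropped, with one reason code each, if the
subject is pregnant, any of the five analysis labs (triglycerides, HDL,
total cholesterol, fasting glucose, fasting insulin) is missing, or age
falls outside 25–64 (both bounds inclusive). Reason precedence is fixed
(pregnancy → missing-lab → age-range) so the log is deterministic. A
missing LDL value does not exclude a record: LDL enters no classification
rule, and the Friedewald estimate `tc − hdl − tg/5` is invalid above
TG 400 mg/dL, where a directly measured value is used when available and a
missing-value marker otherwise. No plausibility truncation is applied
beyond positivity of physical measurements.

**Classification.** ATPIII and IDF rules are applied with their printed
operators kept exactly (waist ≥ 102/88 cm vs strictly > 90 cm; TG ≥ 150;
HDL < 40/50; BP ≥ 130/85; FPG ≥ 100; normal-subject bounds TC ≤ 200 and
BMI ≤ 25 inclusive). Antihypertensive medication counts as hypertension
under both definitions and disqualifies "metabolically normal" status, as
does membership in the diabetic stratum — without the latter, a
history-only diabetic with FPG < 100 could be labelled normal while
carrying the glucose component, which would break the invariant that
normal subjects have zero TG/HDL/BP/FPG components. The diabetic stratum
defaults to interview history OR FPG ≥ 126 mg/dL (the ADA threshold);
`history_only` is selectable because survey reports rarely state which
operationalization was used.

**Weighting.** Post-stratification weights are census share over sample
share per age-decade × sex stratum, rescaled to mean 1 so weighted and
unweighted cohort sizes are comparable. The packaged default census table
is a synthetic stand-in patterned on a young-skewed national pyramid with
a near-even sex ratio; any table can be supplied. Weighted means carry a
SEM based on the Kish effective sample size `n_eff = (Σw)²/Σw²` — a
reliability-weight approximation, not a design-based complex-survey
variance, because the survey's clustering/stratification variables are
not modelled (see Limitations). AUC uncertainty instead uses a
percentile bootstrap over subjects (default B = 2000, seeded; each
resampled subject keeps its weight; replicates that lose an outcome class
are redrawn and counted). Bootstrap calibration was checked by simulation:
over 500 binormal datasets (n = 500, balanced classes, true AUC ≈ 0.70,
B = 500) the nominal 95% interval covered the true AUC 92.6% of the time —
the mild undercoverage typical of percentile intervals at this n.

**Weighted percentile convention.** No single interpolation convention
can simultaneously reduce to the unweighted estimator at every constant
weight *and* equal the expanded-multiset percentile for every integer
weight vector (the two requirements contradict each other already for two
points with weights {2,2}). The convention used is count semantics: tied
values are merged, each distinct value occupies a flat quantile block of
width `(w_j − u)/(W − u)` with `u` the smallest merged weight, and the
quantile function interpolates linearly between blocks. This reproduces
numpy's default (type-7) percentile exactly for any equal weights on
tie-free data, is invariant under integer-weight expansion by
construction, and matches numpy on the expanded multiset whenever some
weight equals 1.

**ROC and cut-points.** Higher score = more likely diseased; a subject
tests positive when score ≥ threshold. Candidate thresholds are the
midpoints between consecutive distinct observed scores plus ∓∞ sentinels,
which enumerate every achievable classification; the trapezoidal AUC of
this curve equals the weighted concordance probability with half credit
for ties (asserted against a brute-force pairwise oracle in the tests).
Cut-points maximize the Youden index `J = Se + Sp − 1` or minimize the
squared corner distance `(1−Se)² + (1−Sp)²` (the squared form is
optimized; its root is monotone in it, so the argmin is identical).
Criterion ties within 1e−12 of the optimum are resolved to the lowest
threshold and the full plateau interval is reported, because real HOMA-IR
criterion curves are flat near their optimum. Both `J` and the `1 + J`
scale are reported, since part of the applied literature prints Youden
values on the latter; published values on either scale are frequently
internally inconsistent with the printed sensitivities/specificities, so
none is treated as a numeric oracle here. Degenerate inputs raise typed
errors: single-class labels (no ROC), all-tied scores (no finite
threshold), out-of-range proportions.

## Synthetic cohort generator

Subjects carry a latent insulin-resistance factor Z ~ N(0,1). Each
clinical variable is `loading·Z + age effect + sex effect + diabetes
shift + independent noise`, exponentiated for the right-skewed labs
(insulin, glucose, triglycerides — log-normal marginals) and left on the
natural scale otherwise. Diastolic pressure additionally receives half of
the systolic noise so the two are correlated; diabetes propensity is
logistic in Z and age with the intercept solved by bisection to hit the
configured marginal fraction (12% default); measurements are rounded to
survey precision; pregnancy (women ≤ 44) and per-lab missingness are
applied last.

The frozen default preset (n = 4233, the raw size before exclusions) was
calibrated once by Monte Carlo and then fixed: ~26% of records excluded
(dominated by missing insulin), weighted MetS prevalence ≈ 29% under both
definitions, nondiabetic HOMA-IR AUC ≈ 0.69 (ATPIII) / 0.69 (IDF),
Youden-optimal cut-offs ≈ 1.9 in nondiabetics and ≈ 4.3 in diabetics. The
diabetic/nondiabetic cut-off separation is an emergent consequence of the
diabetic location shifts in log-glucose (+0.50) and log-insulin (+0.22),
not a hard-coded value. Insulin and glucose deliberately carry no age or
sex effects, so that severing the latent factor (all loadings zero)
leaves only the weak intrinsic score–label link through the shared
glucose measurement: with zero loadings the nondiabetic AUC is ≈ 0.51,
and it rises strictly with the insulin loading.

`planted_truth` computes the generator's implied population quantities
(prevalences, AUCs, criterion-optimal thresholds) by a reference Monte
Carlo run at 10⁶ subjects with a fixed internal seed, missingness and
pregnancy disabled, pushed through the same classification/weighting/ROC
code as any finite cohort. At that size the residual simulation error in
the reference thresholds is of order 0.01.

**What the generator does not emulate.** A single latent factor cannot
reproduce a real survey's full dependence structure (no distinct
lipid/adiposity/pressure sub-factors, no assay batch effects, no
informative missingness — missingness is completely at random, whereas
real lab missingness may correlate with site or subject characteristics),
and census weighting here corrects only age × sex composition, not the
multistage cluster design of an actual national survey. Passing tests
therefore validate the estimators and the pipeline's logic, not any
claim about a real population's cut-off values.

**Cut-point sampling variability.** Because the Youden criterion curve is
flat near its optimum, the empirical argmax converges slowly (cube-root
rather than root-n). By simulation against the 10⁶-subject reference
(20 replicate cohorts per size, default preset, ATPIII/nondiabetic): at a
survey-scale draw of n = 3000 the selected cut-off has mean ≈ 1.93 with
SD ≈ 0.22 (12% relative); at n = 50 000, SD ≈ 0.06 (3% relative) with a
small upward drift from plateau asymmetry. Reported cut-offs from single
survey-sized cohorts should accordingly be read with the plateau interval,
not as point values; this mirrors the plateau explicitly reported in the
applied literature (e.g. optima anywhere in 1.75–2 being equivalent).

## Problem sizes and determinism

The shipped validation suite exercises: oracle equivalences on hundreds
of randomized small fixtures (n ≤ 50); estimator reductions on 100
fixtures; generator recovery on one 50 000-subject cohort against the
10⁶-subject reference; bootstrap coverage on 500 datasets of n = 500; and
byte-identical reruns of the full preset bundle. These sizes keep the
whole suite under half a minute on one CPU while leaving Monte-Carlo
error well inside the asserted tolerances. All randomness flows from
explicit seeds: the pipeline derives one child seed per stochastic stage
(generator, each bootstrap) from its top-level seed via
`numpy.random.default_rng`, and the run manifest records them.

## Known limitations

* SEMs use the effective-sample-size approximation; no Taylor
  linearization or replicate weights (full complex-survey variance
  estimation is out of scope).
* No covariate-adjusted ROC models; the score column is configurable
  (e.g. fasting insulin) and runs through the identical machinery instead.
* No imputation and no unit conversion: mmol/L inputs are rejected, not
  converted.
* Only ATPIII and IDF rule sets; no EGIR/WHO/harmonized-2009 variants,
  no pediatric criteria.
* Whether lipid- or glucose-lowering medication should modify components
  is not modelled (commonly unreported in surveys).
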