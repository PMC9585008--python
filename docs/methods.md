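# Methods

`oliguard` implements an early-warning analysis for severe oliguric acute
kidney injury (AKI) in ICU patients: it converts irregular urine-output and
creatinine charting into hourly trajectories, labels hospital-acquired
oliguric AKI stage 2/3 episodes by KDIGO criteria, and trains two predictors
that score every 12-h observation window for the risk that an episode begins
within the following 24 h. Because the clinical databases such analyses are
developed on are access-controlled, the package ships a synthetic cohort
generator that reproduces the statistical structure the pipeline assumes;
every result the tests and the acceptance script report is computed on
generated data.

## Preprocessing

**Urine resampling.** Nurse-charted urine records carry the volume
accumulated since the previous record, at irregular times. Each record
closes the whole hourly bins since the end of the previously covered bin:
if that silent gap is shorter than 9 h the volume is split equally across
the covered bins; at 9 h or longer the gap bins stay missing and the volume
is assigned to the record's own bin only (attributing it across a long
silent period would be fiction). Bins are half-open `[h, h+1)` anchored at
admission; a record timestamped exactly on a boundary closes the earlier
bin. The split conserves volume exactly over every short gap, and
resampling an already-hourly stream is the identity — both are tested as
invariants. The 9-h threshold is read strictly (`gap < 9`).

**Creatinine filling.** Laboratory creatinine is placed in its hour bin
(latest value wins within a bin) and carried forward through missing bins
for fills spanning less than 4 days, i.e. at most 95 carried bins. Hours
before the first measurement stay missing. µmol/L inputs can be converted
with a flag (factor 88.4); mg/dL is the default and the assumption
elsewhere.

**Ideal body weight.** De-identified exports report height as a 10-cm
range; the midpoint is used. IBW follows the Devine formula (male
`50 + 0.9059·(h − 152.4)` kg, female `45.5 + …`), floored at 40 kg. The
Devine formula is this package's choice; the normalization convention
(ml/h/kg of *ideal* body weight) is standard in KDIGO urine-output work.
Urine output is divided by IBW bin-wise, with missing propagating.

## KDIGO labeling

Urine-output staging uses the consecutive-hours reading of the KDIGO
criteria on the maximal run of observed hours ending at each hour: stage 1
at rate < 0.5 ml/kg/h for 6–12 h; stage 2 for runs strictly longer than
12 h; stage 3 at < 0.3 ml/kg/h for ≥ 24 h or anuria for ≥ 12 h. The "> 12 h"
is strict and the "≥" bounds inclusive, exactly as the criteria are
phrased. Missing hours break runs — no oliguria is assumed where none was
observed — and the staged hour itself must be observed. Creatinine staging
is relative to the baseline (the lowest value across all admissions):
stage 1 at ≥ 1.5× baseline or an absolute rise ≥ 0.3 mg/dL, stage 2 at
≥ 2×, stage 3 at ≥ 3× or ≥ 4.0 mg/dL.

The composite endpoint requires a *simultaneous* reduction in urine output
and rise in creatinine. How simultaneous, and how large a rise, is not
standardized; `oliguard` declares an episode at the first hour with urine
stage ≥ 2 such that creatinine stage ≥ `scr_stage_floor` (default 1) is
reached within ± `co_window_h` (default 12 h). Both are configuration
parameters, and the stage floor in particular materially changes the
labeled prevalence — users comparing against other endpoint definitions
should set it deliberately.

The linear-time run tracker is verified against a quadratic re-scan oracle
on 1,000 random 200-hour sequences with missingness, anuria, and values
straddling both thresholds.

## Cohort construction

Patients are excluded for: stay under 24 h; no urine records or more than
30% missing hourly urine bins; no creatinine measurements; an episode
already satisfied within the first 12 h of the stay (proxy for
community-acquired AKI); or an onset too early to leave one full window
after truncation. These thresholds are package defaults standing in for
study-specific criteria that are not public; each is configurable. The
exclusion log records exactly one decision per patient (a tested partition
invariant).

Case trajectories are truncated to `[0, onset − 6)` before windowing, so
every emitted window — and hence every positive training label — precedes
the event by at least 6 h. Controls contribute their whole stay. Windows
are cut at stride 1 h wherever 12 consecutive observed urine bins exist and
creatinine is available at the window's end (it is a model covariate); the
label is 1 when the detected onset falls in `(end, end + 24]`. Stride,
horizon and the completeness requirement are package choices where the
original design is silent.

## Predictors

Both models are scikit-learn-style estimators and train only on windows
from training-split patients (splits are patient-level, stratified by
event status, seeded — windows of one patient never straddle a split).

*Logistic regression* uses 11 deterministic features of the window and
covariates: min, max, mean, last value and least-squares slope of the
12 urine values, hours below 0.5 and below 0.3 ml/kg/h, current
creatinine, creatinine/baseline ratio, ordinal age group, and sex. The
exact feature set of the original models is not public; this set is a
reconstruction and is documented as such. Fitting is unpenalized maximum
likelihood on standardized features (lbfgs, tolerance 1e-8, 100
iterations); perfect separation is detected (non-overlapping training
scores) and handled by refitting with a tiny L2 penalty plus a warning.
Coefficient recovery is tested on generated one-feature data (n = 50,000,
slope 2.0 recovered within ±0.05).

*Convolutional network.* Three parallel 1-D convolution branches with
kernel sizes 3, 6 and 12 (8 filters each, valid padding, ReLU, global max
pooling) read the standardized 12-value urine sequence; pooled outputs are
concatenated into one hidden ReLU layer (16 units) and a sigmoid output —
about 1,000 parameters. It is implemented directly in numpy
(forward/backward, Adam, class-weighted binary cross-entropy, inverse-
frequency class weights), with early stopping on a patient-level
validation split (15%, patience 8, selection by validation AUC). All
randomness flows from a single seed; a fixed seed reproduces weights and
predictions bit for bit on one CPU thread. At this parameter count a CPU
trains on tens of thousands of windows in seconds, and both the permutation
null (shuffled labels ⇒ held-out AUC in [0.45, 0.55]) and the separable
regime (external AUC > 0.9) are exercised in the test suite.

The prediction horizon of the convolutional model is set to the same 24 h
as the logistic model for comparability; the original description leaves it
unquantified.

## Evaluation

ROC curves sweep every unique score (no interpolation dropping); AUC is
trapezoidal and equals the Mann–Whitney concordance probability with ties
counted half — asserted against an exhaustive pair-counting oracle. The
AUC standard error uses the Hanley–McNeil formula. Operating points:
fixed sensitivity (maximum specificity among thresholds with sensitivity
≥ 80%, ties toward the higher threshold) and the knee point (minimum
Euclidean distance to the ideal ROC corner, ties toward higher
sensitivity; Youden's J optionally). LR+ = sens/(1 − spec) and
LR− = (1 − sens)/spec, with infinities flagged at the poles. Patient-level
scores aggregate window scores by maximum (alert semantics; mean
optional). Report cells round to two decimals, half away from zero, and
LR cells are re-derived from each row's own unrounded sensitivity/
specificity so rendered tables are internally consistent by construction.

The package also audits the published reference tables it mirrors
(`oliguard validate-tables`): each printed LR cell is checked against the
interval of LRs achievable from any sensitivity/specificity pair within
the half-percentage-point rounding band of the printed integers. Two LR−
cells of the sparse-acquisition (eICU) rows fall outside their achievable
intervals and are flagged as likely typographical; all sixteen other cells
are consistent.

## Synthetic cohort generator

The generator emulates the features the pipeline depends on, with defaults
chosen once to mirror the published cohort descriptions:

| parameter | default | what it emulates |
|---|---|---|
| urine inter-record interval | gamma(2), median 1.3 h (dense) / 2.4 h (sparse) | nurse charting frequency of the two regimes |
| creatinine interval | gamma(2), median 16.2 h / 23.2 h | laboratory sampling frequency |
| stay length | log-normal, median 40 h / 120 h, σ = 0.8 | skewed ICU stay distributions |
| event prevalence | 4.2% / 3.0% | episode rates of the two cohorts |
| age mix, sex | six-band weights; 71.1% / 63.2% male | demographic tables |
| healthy urine rate | per-patient mean ~N(1.5, 0.35), hourly noise 0.25, floor 0.6 ml/kg/h | normal diuresis with charting noise |
| oliguric phase | depth ≤ 0.25 ml/kg/h, duration 16–36 h, prodrome ~36 h, recovery 12 h | progressive decline into sustained oliguria |
| creatinine response | baseline ~N(0.85, 0.15) mg/dL, 2.5× rise ramping over 4 h starting −6…+2 h around phase onset | the simultaneous-criteria signature |

Events are placed ≥ 24 h after admission and end ≥ 12 h before discharge;
stays for event patients are redrawn until the phase fits. Healthy hourly
rates never drop below 0.6 ml/kg/h, so non-event patients cannot satisfy
the stage 2/3 urine criterion — by construction, not by chance. One
"confirmatory" creatinine sample is inserted 4–10 h after phase onset with
a guaranteed ≥ 2× value: with a median lab interval of 16 h, random
sampling alone could miss the ±12 h co-occurrence window, which would make
injected events unlabelable for reasons that have nothing to do with the
pipeline. Ground truth goes to a separate `truth.csv` the pipeline never
reads.

Because KDIGO stage 2 requires more than 12 consecutive oliguric hours,
the *event onset* is necessarily later than the start of the decline. The
truth table therefore records `true_onset_hour` as the first hour at which
the composite stage 2/3 condition holds on the generator's own true
(pre-sampling) hourly curves — computed by running the staging rules on
those curves — and keeps the phase start separately as
`oliguria_start_hour`. Onset-recovery checks compare the pipeline's
detected onset against `true_onset_hour`.

**What the generator does not model:** comorbidities, medications,
diuretic challenges, renal replacement therapy, mortality processes
coupled to AKI, readmissions, non-oliguric AKI, transient oliguria that
resolves before 12 h, and measurement artifacts (urimeter errors, charting
typos). Passing tests therefore demonstrate that the pipeline implements
its stated rules correctly and that the models can learn a progressive
oliguric signature under realistic charting noise — they do not
demonstrate clinical performance on real ICU data, where the decline into
oliguria is more heterogeneous and the discriminative signal weaker.

## Numerical and design choices

- Strict/inclusive boundary semantics (9 h, 96 h, "> 12 h", "≥ 24 h",
  "≥ 12 h") are tested explicitly at the boundaries.
- Degenerate inputs: empty cohorts generate and write header-only files;
  zero-event cohorts abort at model fitting with a single-class error;
  patients with no windows contribute nothing and are logged.
- The global seed fans out to per-stage seeds via `SeedSequence.spawn`, so
  any stage can be reproduced in isolation from the config snapshot.
- Tie-breaks: fixed-sensitivity points prefer the higher threshold; knee
  points the higher sensitivity; within-bin duplicate creatinine values
  keep the latest.
- Problem sizes: the test suite and the acceptance script run the full
  study at 800 training / 500 external patients and audit truth recovery
  on a 2,000-patient cohort; at these sizes the external ROC already has
  hundreds of positive windows and results are stable across seeds. The
  generator scales linearly for larger studies.

## Known limitations

- The labeled endpoint is sensitive to the undocumented `scr_stage_floor`
  choice; prevalence and AUC are not comparable across different floors.
- The eICU-like sparse regime occasionally produces ≥ 9 h silent gaps
  inside an oliguric run, breaking it and delaying detection; this is a
  faithful consequence of the imputation rule, not a defect.
- Hanley–McNeil assumes independent observations; window-level AUC SEs are
  anti-conservative because windows within a patient are correlated.
  Patient-level metrics avoid this; a seeded patient-resampling bootstrap
  is the natural extension.
- The numpy network trains full-batch gradients per minibatch on one
  thread; it is deliberately small and is not a framework replacement.
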