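# Methods

## The estimating equation

Estimated GFR (ml/min/1.73 m², creatinine in mg/dl, age in years) is a
piecewise power law `k · (SC/τ)^c · a^Age`, with the branch chosen by sex
and by which side of the sex-specific threshold τ the creatinine falls on.
Threshold values themselves resolve to the at-or-below branch. Two
consequences of the published coefficients are reproduced deliberately
rather than smoothed over:

* the female equation steps **down** across τ = 1.2 mg/dl (92 → 79 at the
  age-zero value), leaving an unreachable band of eGFR values
  [79·0.994^Age, 92·0.994^Age);
* the male equation steps **up** across τ = 1.0 mg/dl at age 0
  (98 → ~105); because the two male branches carry different age bases
  (0.996 vs 0.993) the jump shrinks with age and inverts around age 50.

Ages are accepted on [0, ∞) — the equations are defined everywhere — but a
`AgeRangeWarning` is emitted outside [18, 100] since the cohorts the
coefficients describe are adult. Creatinine is handled internally in mg/dl;
µmol/l is accepted at the I/O boundary (factor 88.4). eGFR is never rounded
internally; the report renderer rounds metrics to one decimal and p-values
to three.

The imaging-GFR calibration is affine, `0.167 + 1.057 × imaging GFR`, with
both coefficients exposed in `CalibrationCoefficients`.

## Member models and the ensemble

All members share the covariates age, male indicator and ln(creatinine)
(the equation is log-linear in creatinine, so the log transform puts the
learners on the same natural scale) and predict measured GFR.

* **ANN** — one hidden layer of 8 logistic units (the smallest standard
  architecture adequate for three covariates), adam optimiser, early
  stopping on an internal 20% validation split, inputs and target
  z-standardised with development-set statistics.
* **SVM** — epsilon-insensitive RBF support-vector regression (ε = 0.1 on
  the standardised target); C ∈ {1, 10, 100} and γ ∈ {0.03, 0.1, 0.3, 1}
  chosen by seeded 5-fold cross-validated grid search on squared error.
* **regression** — the fixed piecewise equation; no training.

Standardisation statistics live inside the serialised model state, so
prediction needs no external context. After fitting, the learned parameters
are extracted from the fitting library into plain JSON and **all**
predictions are computed by a numpy forward pass from that state; this is
what makes a reloaded model bit-identical to the original, not merely
close. Learner predictions are floored at 1 ml/min/1.73 m² so P30 ratios
stay defined; the regression member cannot produce values that low on
physiological inputs.

The ensemble is the element-wise arithmetic mean of its members'
prediction vectors — permutation-invariant and bounded by the member-wise
extremes. When member errors are unbiased, independent and of equal
spread the averaged error has ~1/√3 of the member spread, which is the
precision gain the ensemble test quantifies.

## Validation framework

Differences are `mGFR − eGFR` (positive bias = underestimation); the
direction is a switch because conventions differ across the literature.
Bias is the sample median, precision the IQR, both under linear
interpolation of order statistics (numpy's default quantile rule; with raw
cohort data unavailable no printed table can adjudicate between quantile
conventions, so one is fixed and documented). P30 reads "within 30%"
inclusively (|eGFR − mGFR| ≤ 0.30·mGFR).

Confidence intervals are percentile bootstrap over patients (default
B = 2000), resampling all aligned vectors jointly. Paired comparisons
against the benchmark:

* **bias** — two-sided Wilcoxon signed-rank on per-patient `d_A − d_B`,
  zeros dropped; exact null for ≤ 25 untied pairs, otherwise normal
  approximation with tie and continuity correction;
* **precision** — paired bootstrap: each draw resamples patients once and
  evaluates Δ* = IQR(A*) − IQR(B*); p = 2·min(P(Δ* ≤ 0), P(Δ* ≥ 0));
* **accuracy** — McNemar on the P30 hit indicators: exact binomial when
  the discordant count b + c < 25, continuity-corrected chi-square
  otherwise, p = 1 when b + c = 0.

No multiple-testing adjustment is applied; each comparison is reported at
α = 0.05. Subgroups stratify on **measured** GFR with half-open bins
[lo, hi), default edges 30 and 60; an empty stratum reports n = 0 with
absent metrics. All resampling derives from one top-level seed via numpy
`SeedSequence` spawning in a fixed (model, stratum, metric) order, which is
what makes whole reports reproducible bit-for-bit.

## Synthetic cohorts

The generator emulates a referral CKD population: measured GFR from a
five-bin stage mixture (uniform within bin; support 10–175 ml/min/1.73 m²,
matching the plausible clinical range), truncated-normal age on [18, 90],
Bernoulli sex and diabetes status (diabetes is recorded for cohort-table
fidelity but used by no model). Creatinine is obtained by inverting the
piecewise equation at the drawn GFR and multiplying log-normal noise
exp(ε), ε ~ N(0, σ²), floored at 0.1 mg/dl. Presets parameterise the
mixture and marginals to the development (stage counts 10/99/275/345/273 of
1002, age 55.7 ± 15.0, 56.9% male) and external-validation cohorts
(9/94/149/123/42 of 417, age 51.3 ± 16.0, 62.8% male).

Because of the female range gap and male overlap noted above, the GFR draw
is uniform on bin ∩ attainable-set (computed per record as explicit
sub-intervals, so stage proportions are preserved exactly and no rejection
loop is needed), and the at-or-below branch is preferred in the male
overlap. At σ = 0 the equation therefore inverts the generator exactly for
every record.

Two variants control the age term:

* default (`age_coupled=False`) — the age effect is folded into the
  per-sex scale, i.e. omitted from the creatinine model. The estimating
  equation then carries a realistic systematic age-related error on
  generated data, emulating equation misspecification on an external
  population; trained learners can and do outperform the fixed equation in
  this regime.
* `age_coupled=True` — the age term enters generation, the equation is the
  exact noiseless inverse, and at σ = 0 validation returns zero bias, zero
  IQR and P30 = 1. This variant underlies the exact-inversion and
  parameter-recovery tests.

Default noise is σ = 0.2 (≈20% coefficient of variation of creatinine
given GFR, standing in for all unmodelled physiological variation in the
filtration marker).

What the simulator does **not** emulate: any dependence of GFR on age or
sex beyond the equation itself, comorbidity structure, assay drift,
within-patient repeat measurements, or the measurement physics of isotope
imaging ("measured" GFR is produced directly). Passing tests on synthetic
cohorts therefore demonstrates the correctness and stability of the
machinery, not clinical performance on real populations.

### Parameter recovery

`recover_coefficients` refits the power law per branch. Since the
generative noise sits in creatinine given GFR, ordinary least squares is
run with ln(SC/τ) as the response — `ln(SC/τ) = b0 + b1·ln(mGFR) + b2·Age`
— and the branch coefficients recovered as c = 1/b1, ln k = −b0/b1,
ln a = −b2/b1. Regressing ln(mGFR) on ln(SC) instead attenuates the
exponent by the classical errors-in-variables factor, materially so on the
at-or-below branches whose attainable GFR range is narrow. Branches with
fewer than 30 records are reported unfitted rather than raising.
Single-branch experiment cohorts keep measured GFR a ×1.3 margin from the
branch boundary so creatinine noise essentially never pushes records across
the threshold into the sibling branch.

## Problem sizes in the shipped tests

The test suite exercises: oracle equivalence on 1000 random inputs per
statistic; bootstrap coverage with 500 replicates of n = 200 at B = 2000;
recovery on 100 noisy replicates of n = 2000 per branch; the ensemble
property on 200 replicates of n = 400; and the end-to-end pipeline at
n = 200/150 with B = 200. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping the suite quick.

## Known limitations

* The ANN and SVM members are reasonable small-tabular-regression defaults,
  not a tuned architecture search; their hyperparameters are configurable.
* The precision comparison's bootstrap p-value is an achieved significance
  level from the resampled difference distribution, not a studentised
  bootstrap test; for very small strata it is conservative.
* The descriptive two-cohort comparison (`gfrens compare`) reports
  means/SDs and proportions only; the two preset cohorts are independent
  samples, so no paired testing is attempted between them.
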