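# gfrens

Estimating glomerular filtration rate (GFR) from serum creatinine, age and
sex — and validating such estimators — for nephrology and biostatistics use.
The package implements:

* a **four-branch piecewise power-law estimating equation**

  $$\mathrm{eGFR} = k \times (\mathrm{SC}/\tau)^{c} \times a^{\mathrm{Age}}$$

  with sex-specific creatinine thresholds τ (1.2 mg/dl women, 1.0 mg/dl
  men) and branch coefficients

  | sex | SC (mg/dl) | k | c | a |
  |---|---|---|---|---|
  | female | ≤ 1.2 | 92 | −0.534 | 0.994 |
  | female | > 1.2 | 79 | −0.516 | 0.994 |
  | male | ≤ 1.0 | 98 | −0.450 | 0.996 |
  | male | > 1.0 | 105 | −0.640 | 0.993 |

* **ensemble estimation**: ANN (single hidden layer) and RBF support-vector
  regression members trained on a development cohort, combined with the
  equation by element-wise arithmetic averaging of predicted GFRs;
* the standard **equation-validation framework**: bias (median of
  mGFR − eGFR), precision (IQR of the differences), P30 accuracy
  (fraction within ±30% of measured GFR), 95% percentile-bootstrap CIs
  (2000 resamples), paired Wilcoxon signed-rank / bootstrap-IQR / McNemar
  comparisons against a benchmark model, and subgroup summaries stratified
  by measured GFR (<30, 30–60, ≥60 ml/min/1.73 m²);
* a **synthetic CKD cohort simulator** (stage-mixture measured GFR,
  truncated-normal age, Bernoulli sex, creatinine from a noisy inverse
  power law) so the whole pipeline runs without patient data, including
  presets that match the marginals of a 1002-patient development and a
  417-patient external-validation cohort.

## Worked example

Library use — one patient at the female branch threshold, then with age:

```python
>>> from gfrens import PatientRecord, estimate_gfr_regression
>>> estimate_gfr_regression(PatientRecord("p1", age=0, sex="female", scr=1.2))
92.0
>>> estimate_gfr_regression(PatientRecord("p1", age=50, sex="female", scr=1.2))
68.09371790238397
```

92.0 is the female branch's scale coefficient (the creatinine ratio and age
terms are both 1); at age 50 the age term 0.994⁵⁰ multiplies it down to
68.1 ml/min/1.73 m².

Full pipeline from the shell — simulate both cohorts, train the two
learners, layer predictions for all four models into one file, evaluate:

```sh
gfrens simulate --preset development --n 400 --seed 7 --out dev.csv
gfrens simulate --preset validation  --n 250 --seed 8 --out val.csv
gfrens train --input dev.csv --model ann --seed 7 --out ann.json
gfrens train --input dev.csv --model svm --seed 7 --out svm.json
gfrens estimate --input val.csv --model regression --output p1.csv
gfrens estimate --input p1.csv  --model ann.json   --output p2.csv
gfrens estimate --input p2.csv  --model svm.json   --output p3.csv
gfrens estimate --input p3.csv  --model ensemble \
       --members regression,ann.json,svm.json --output pred.csv
gfrens evaluate --input val.csv --pred pred.csv --benchmark regression \
       --bootstrap 2000 --seed 1 --format markdown --out report.md
```

The report's overall column from this exact run:

| model | bias (95% CI) | precision (95% CI) | P30 % (95% CI) |
|---|---|---|---|
| regression | 11.7 (10.2 to 13.1) | 11.0 (9.1 to 13.3) | 59.2 (52.8 to 64.8) |
| ann | −0.4 (−1.3 to 0.6) ‡ | 8.2 (6.8 to 9.7) ‡ | 96.0 (93.6 to 98.4) ‡ |
| svm | −1.7 (−2.6 to −0.9) ‡ | 7.8 (6.3 to 9.6) ‡ | 94.8 (92.0 to 97.2) ‡ |
| ensemble | 2.9 (2.0 to 3.7) ‡ | 8.2 (6.5 to 9.6) ‡ | 98.8 (97.2 to 100.0) ‡ |

Bias and precision are in ml/min/1.73 m²; ‡ marks a paired comparison with
the regression benchmark significant at p < 0.05. Under the simulator's
default conditions the fixed equation carries a systematic age-related
error that the trained members learn around, so they dominate it here; with
`--age-coupled` generation the equation is correctly specified and all four
models perform similarly (see `docs/methods.md`).

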