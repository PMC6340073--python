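# lipi

Derivation, scoring, and validation of a compound clinical–immunological
**infection-predictive index** for systemic lupus erythematosus (SLE)
cohorts.

SLE patients are unusually prone to infection, and much of that risk is
driven by the disease's own immune abnormalities rather than by treatment
alone. Given a longitudinal cohort table — immunophenotype counts
(×10⁶/L), monocyte TLR2 mean fluorescence intensity, disease-activity
scores, treatment per visit, and an infection outcome — this package:

* estimates per-feature infection risk as risk ratios (log-binomial with a
  modified-Poisson fallback; logistic odds ratios behind a flag) with Wald
  95% CIs and likelihood-ratio screening p-values, and selects explanatory
  models by AIC;
* picks dichotomization cutoffs on empirical ROC curves by the
  **closest-to-corner criterion**, argmin over thresholds t of
  (1 − sens(t))² + (1 − spec(t))²;
* assigns integer points by RR-magnitude rank (3 for the strongest effect,
  2 for the second, 1 for the rest) and composes them into a scored index
  with a compound threshold;
* evaluates any index or single dichotomized variable on baseline and
  nested case-control data: sensitivity/specificity with exact
  (Clopper–Pearson) 95% CIs, LR+ and LR−, and AUC with DeLong CIs and
  DeLong AUC comparison.

The published four-variable rule set ships as a packaged index
(`lipi.published_lipi()`): cyclophosphamide use +3, Th17 > 8 ×10⁶/L +2,
B cells < 60.5 ×10⁶/L +1, monocyte TLR2 MFI < 1,364 +1; score > 1.5
predicts infection within a year.

Because the underlying patient-level data are not public, a first-class
synthetic-cohort generator (`lipi.synthetic`) reproduces the study's
statistical shape — log-normal feature marginals fitted to the published
median/IQR summaries, within-patient correlation, a calibrated logistic
outcome model hitting the published 32.7% one-year infection incidence,
and the 1–3-month pre-infection nested case-control construction — so
every pipeline stage is testable end to end. See `docs/methods.md` for the
full model description and limitations.

## Worked example

```python
import lipi

# A synthetic cohort under the strong-effect outcome model.
config = lipi.default_config(n_patients=400, seed=7)
cohort = lipi.generate_cohort(config)

# Derive an index from scratch: screen, ROC cutoffs, points, threshold.
index = lipi.build_index(
    cohort, ["cyclophosphamide", "th17", "b_cells", "tlr2_mfi"])
for rule in index.rules:
    print(rule.feature, rule.direction, rule.cutoff, f"+{rule.points}")
print("threshold:", index.threshold)
```

prints (cutoffs are data-driven midpoints, so they vary with the cohort):

```
cyclophosphamide present None +3
th17 greater 4.2394... +2
b_cells less 124.06... +1
tlr2_mfi less 8176.3... +1
threshold: 1.5
```

The drug exposure ranks first by RR magnitude (+3), the Th17 analog second
(+2), and the two protective features (RR < 1) get +1 each; the compound
threshold 1.5 means two or more points predict infection.

Scoring one patient with the packaged published rules:

```python
index = lipi.published_lipi()
lipi.lipi_score({"cyclophosphamide": True, "th17": 11,
                 "b_cells": 47, "tlr2_mfi": 1500}, index)
# {'score': 6, 'predicted': True}   # 3 + 2 + 1 + 0, strictly above 1.5
```

Evaluating the published index on the synthetic cohort (baseline and
nested case-control):

```python
reports = lipi.evaluate_models(cohort, [index])
print(lipi.reports_to_frame(reports).round(3))
```

```
  model    dataset  cutoff  lr_pos  lr_neg    auc   sens    spec      p
lipi_v1   baseline     1.5   2.202   0.619  0.759  52.99   75.94  0.000
lipi_v1     nested     1.5   1.712   0.731  0.627  46.99   72.56  0.000
```

(sens/spec in percent with exact CIs in the full frame; the p-value is the
DeLong test of AUC = 0.5). The published cutoffs transfer only roughly to a
synthetic cohort — its marginals match the published medians/IQRs, not the
real joint distribution — which is exactly why the derivation pipeline
exists.

The same flow is available from the shell:

```sh
lipi simulate --seed 7 --n 400 --out run/
lipi derive   --cohort run/cohort.csv \
              --features cyclophosphamide,th17,b_cells,tlr2_mfi --out run/
lipi score    --cohort run/cohort.csv --index run/index.json --out run/
lipi evaluate --cohort run/cohort.csv --index run/index.json --out run/
```

Every artifact embeds the seed, package version, and input digests in
comment headers; identical inputs give byte-identical outputs.

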