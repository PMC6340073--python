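# Methods

## Problem and model

`lipi` implements a compound clinical–immunological risk score for
predicting infection within one year of follow-up in systemic lupus
erythematosus (SLE) patients, together with the full derivation and
validation pipeline around it. The published rule set (shipped as
`lipi_v1.json`) dichotomizes four variables and sums integer points:

| variable | risk side | points |
|---|---|---|
| cyclophosphamide use | present | +3 |
| Th17 cells (×10⁶/L) | > 8 | +2 |
| B cells (×10⁶/L) | < 60.5 | +1 |
| monocyte TLR2 MFI (AU) | < 1,364 | +1 |

A total score strictly greater than 1.5 predicts infection. The pipeline
that produces such an index from a cohort has four stages, each usable on
its own:

1. **Association.** Per-feature infection risk as a risk ratio (RR). The
   default regression is log-binomial (coefficients exponentiate to RRs per
   unit); when it fails to converge — frequent with continuous covariates,
   because the log link does not respect the binomial mean constraint — the
   modified-Poisson estimator (Poisson working model, HC0 sandwich
   variance) targets the same RR. Logistic regression (odds ratios) is
   available via `link="logistic"`. Confidence intervals are log-scale
   Wald. The per-feature *p*-value, however, is a likelihood-ratio
   (drop-one) test whenever the fit has a true likelihood: with covariates
   as right-skewed as lymphocyte subset counts (log-scale SD ≈ 1.2), the
   Wald statistic of the log-binomial fit is anti-conservative (observed
   type-I rate 9–11% at α = 0.05 in our null simulations) while the LRT
   stays at 4–5%. The modified-Poisson fallback has no likelihood, and it
   is triggered by exactly the samples where log-binomial inference
   misbehaves — conditional on fallback, the robust Wald *p* false-flagged
   most null fits — so its *p* comes from the logistic LRT of the same null
   hypothesis; robust Wald remains the last resort. `select_model_by_aic`
   compares candidate feature sets on the logistic likelihood: AIC is only
   meaningful within one likelihood family, which rules out mixing
   binomial fits with Poisson-fallback fits.

2. **Cutpoints.** Empirical ROC over candidate thresholds at midpoints
   between consecutive distinct observed values (plus ±∞ sentinels), so a
   selected rule prints as a strict inequality ("> 8", "< 60.5") that can
   sit between observed measurements. The cutoff minimizes the
   closest-to-corner criterion (1 − sens)² + (1 − spec)². Ties break toward
   higher specificity (the index is a rule-in test), then toward the more
   extreme threshold (fewer test-positives). Youden's J is provided for
   comparison only. Direction is auto-detected from concordance (cases
   tending larger → greater-is-risk) unless given.

3. **Point assignment.** Features are ranked by effect magnitude
   m = max(RR, 1/RR), so protective effects compete symmetrically: the top
   rank earns 3 points, the second 2, every remaining feature 1 — the
   published pattern 3/2/1/1 generalized conservatively. A magnitude tie
   across the 3/2 or 2/1 boundary is ambiguous and raises an error that an
   explicit override must resolve. The compound threshold defaults to the
   second-ranked rule's points − 0.5, reproducing "> 1.5" for the 3/2/1/1
   point set; it is always overridable.

4. **Evaluation.** Sensitivity and specificity in percent with exact
   Clopper–Pearson 95% CIs (beta quantiles; the published intervals are
   reproducible only by the exact method — e.g. 76.84 is (α/2)^(1/14)).
   LR+ = sens/(1 − spec) with an infinity flag at spec = 1; LR− =
   (1 − sens)/spec, undefined at spec = 0; an optional 0.5 continuity
   correction applies to the likelihood ratios only. AUC is tie-adjusted
   pair counting; its CI is DeLong by default, with an untruncated
   Hanley–McNeil normal approximation retained because some published
   intervals exceed 1 (such bounds are flagged). `compare_auc` is the
   DeLong paired (or unpaired) z-test; the per-row *p* in model-comparison
   tables tests AUC = 0.5 by the same standard error.

## Synthetic cohorts

Patient-level data behind the index are not public, so every stage is
exercised on synthetic cohorts that emulate the published summaries.

* **Marginals.** Each positive feature is log-normal with μ = ln(median)
  and σ the mean of the two one-sided quartile estimates
  ln(q3/median)/z₇₅ and ln(median/q1)/z₇₅ (z₇₅ = Φ⁻¹(0.75) ≈ 0.6745) — the
  minimal symmetric compromise for asymmetric printed quartiles; both
  one-sided estimates are retained for checks. Default marginals are the
  published baseline SLE medians/IQRs (Th17 4 (2–10.5), B cells 163.5
  (55.75–352.25), TLR2 MFI 9,567 (5,552–13,848), LDG 43 (19–110),
  lymphocytes 1,084 (686–1,659)). The score table prints different B-cell
  medians (47 vs 157) than the baseline table (88 vs 253 by outcome); since
  the source dataset of those columns is unstated, both are exposed as
  presets rather than guessed between.
* **Within-patient correlation.** One shared patient-level standard normal
  factor on the log scale with weight √ICC (default ICC 0.5, configurable);
  the marginal distribution at every visit is unchanged.
* **Outcome.** Logistic on ln(baseline feature values) and drug indicators.
  The strong-effect preset (+2 ln Th17, −2 ln B cells, −1 ln TLR2 MFI, +1.5
  cyclophosphamide) encodes the direction and ordering of the published
  associations for recovery simulations; the null preset zeroes all
  effects. The intercept is calibrated by bisection on the sampled linear
  predictors so that the expected prevalence equals the published one-year
  incidence of 32.7% (no closed form exists under log-normal covariates).
  Cyclophosphamide exposure is Bernoulli(0.109), the published exposure
  fraction, constant across visits. Visits default to days 0/30/90/180 and
  follow-up to 365 days; infected patients get an infection day uniform on
  [1, 365].
* **Nested case-control.** Each infected patient contributes the latest
  visit in the closed window [infection day − 90, infection day − 30] (the
  "1–3 months before infection" reading); cases with no such visit are
  dropped with a warning. Controls (uninfected patients) are time-matched
  by contributing the visit at the scheduled index most often selected
  among cases (ties to the earlier index), one row per control.

What the generator does **not** emulate: time-varying treatment, flare
dynamics, informative visit timing, missingness, measurement error in
gating, and correlations *between* features (features are conditionally
independent given the patient factor). Passing recovery tests therefore
shows the pipeline recovers structure it is pointed at under clean
conditions; it does not certify performance on real cohorts.

## Numerical choices and degenerate inputs

* Quartiles: linear interpolation (NumPy default); baseline = first visit.
* Adjusted mean SLEDAI: trapezoidal time-weighting over the visit span,
  with a step (last-observation-carried-forward) rule selectable; a single
  scored visit returns its value.
* All-tied paired comparisons return p = 1 with a warning instead of
  erroring, so batch summary tables never abort.
* Mann–Whitney uses the exact distribution for small tie-free samples
  (combined n ≤ 25), asymptotics otherwise; chi-square is Pearson without
  continuity correction.
* 2×2 risk ratios with a zero event cell are an error unless the optional
  0.5 continuity correction is enabled.
* Continuous covariates are standardized internally before GLM fitting and
  coefficients mapped back (an affine recoding; the likelihood, hence AIC,
  is unchanged). A standardized coefficient beyond ±15 is reported as
  separation, naming the covariate.
* Missing feature values are handled complete-case per analysis.
* Seeds: all generation flows through one `numpy` Generator seeded from the
  configuration; identical configurations produce byte-identical cohorts.

## Simulation sizes

Recovery simulations use n = 2,000 patients over 50 seeds (point
assignment) and 100 seeds (cutoff recovery); null calibration uses 200
replicate cohorts of n = 300; prevalence calibration is checked at
n = 5,000. Marginal round-trips use 10⁶ direct draws.

## Known limitations

* The closest-to-corner cutoff, like any empirical-argmin threshold
  estimator, fluctuates by a few order statistics around a step-risk
  change point even at n = 2,000: in our simulations the estimate falls
  within the single bracketing order-statistic gap of the true change
  point in roughly two thirds of replicates (and concentrates within a few
  gaps). Expecting within-one-gap recovery in ≥95% of replicates is not
  attainable for a continuously distributed feature; the corresponding
  acceptance check is left failing by design rather than weakened, and the
  acceptance script reports the measured rate.
* The corner criterion's population optimum coincides with a risk step
  only when the step is "balanced" (e.g. at the median under 0.8/0.1 event
  rates); for steps far in a tail the criterion targets a different
  threshold. This is a property of the criterion, not of the search.
* Published RRs are not re-derivable from the printed 2×2 counts in every
  case (the drug-exposure RR 3.678 likely stems from a repeated-measure
  model whose details were never published); the packaged
  index uses the published points as given, and `rr_from_2x2` reproduces
  the count-based 2.33.
* A published LR− of 0.001 alongside sens 90% / spec 100% is not
  reproducible by the standard formula, which gives 0.10; the
  implementation returns the formula value.
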