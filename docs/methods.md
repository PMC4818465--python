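# Methods

## The metabolic-syndrome construct

MetS is coded present when at least three of five risk factors are
present. Thresholds follow a modified NCEP/ATP III rule set suited to
cohorts where lipids are released only as decile ranks and glycemia is
measured by HbA1c rather than fasting glucose:

| component        | rule (strict inequalities where shown)                  |
|------------------|---------------------------------------------------------|
| high waist       | men > 102 cm, women > 88 cm                             |
| high blood pressure | SBP ≥ 135 **or** DBP ≥ 85 mm Hg (default)            |
| hyperglycemia    | HbA1c > 5.7 %                                           |
| high TG          | men: within-sex decile ≥ 8; women: ≥ 9 (10 = highest)   |
| low HDL          | men: decile ≤ 2; women: ≤ 3                             |

The SBP threshold of 135 is deliberately retained as the default even
though the common ATP III value is 130; `bp_threshold="standard"`
switches to 130. The decile rules pin high-TG prevalence at 30 %
(men) / 20 % (women) and low-HDL at 20 % / 30 % by construction —
they stand in for absolute lipid cutoffs and were chosen to match
published young-adult prevalences of hypertriglyceridemia and low HDL.
`compute_deciles` is rank-based (ties share the lower decile) and
sex-specific by default; a pooled mode exists because release formats
are sometimes ambiguous about the ranking population.

## Cutpoint derivation

Positivity is `WHtR > c` (strict) everywhere — one source of boundary
truth shared by derivation, sweep tables, validation and prediction.

* **Unweighted.** Candidates are all unique observed WHtR values (an
  exhaustive search over distinct empirical ROC points; a midpoint mode
  exists and changes only the reported value, not the classification).
  Ties in J resolve to the smallest cutoff, which preserves
  sensitivity — the clinically conservative choice for a screening
  marker; `tie_break="specificity"` inverts this. A maximal J of zero
  is flagged degenerate (the marker does not discriminate in the `>`
  direction).
* **Survey-weighted.** Contingency-table cells are sums of sampling
  weights. The search is two-stage: a coarse grid (default 0.50–0.60,
  step 0.01) locates the neighbourhood of the optimum; a fine grid
  (argmax ± 0.01, step 0.001) pins the reported cutoff. The defaults
  mirror the plausible clinical range for adult WHtR cutoffs and are
  fully overridable; an argmax on the coarse boundary triggers one
  widen-and-rerun (by the full grid span) before warning. Both stage
  tables are retained in the result for reporting.

## Variance estimation

* iid tables: Wilson score intervals for proportions; Simel-style
  log-normal intervals for likelihood ratios; Woolf's log interval for
  the odds ratio with a 0.5 continuity correction only when a cell is
  zero; J gets a normal interval from the summed Wald variances. These
  formulas assume iid counts and are flagged (`iid_cis=False`) when
  applied to weight sums.
* Design-based rates: a rate is a ratio of weighted totals
  R = X̂/Ŷ; its Taylor-linearized score is wᵢ(xᵢ − R yᵢ)/Ŷ. Scores are
  summed to PSU totals and the variance is the stratified between-PSU
  sum of squares with the usual n_h/(n_h − 1) scaling. Derived measures
  (J, log PLR, log NLR, log OR) combine the sens/spec scores through
  the chain rule *before* clustering, so their intervals keep the
  design covariance between sensitivity and specificity. Intervals are
  est ± 1.96·SE (truncated to the parameter range); with very few PSUs
  this normal quantile undercovers slightly — a t-quantile refinement
  was deliberately left out to keep the contract simple, so designs
  should carry a few dozen PSUs before the nominal level is trusted
  (the test suite demonstrates ~94–95 % coverage at 60 PSUs).
* Lonely PSUs: a stratum with a single PSU contributes its squared
  deviation from the grand PSU mean (certainty-unit treatment) with a
  warning, keeping small simulated designs estimable.

## AUC

Unweighted AUC is the Mann–Whitney statistic computed from midranks
(ties count ½) with a DeLong placement-based variance. The weighted AUC
follows the survey-logistic route: fit a weight-incorporating logistic
model of the outcome on the predictor and compute the concordance of
its fitted probabilities over case/non-case pairs, each pair weighted
by the product of the two participants' weights, ties ½. With unit
weights this reduces exactly to the Mann–Whitney value (the logistic
transform is monotone), which the tests assert to 1e-6. Pair-product
weighting is the natural design-consistent estimator of the population
pairwise exceedance probability; no closed-form design CI is attached
to the weighted AUC.

## Logistic validation

The adjusted model predicts MetS from the cutoff indicator, race
(categorical, nonHispanic Caucasian reference), smoking days
(continuous), age (continuous) and, in pooled fits, sex. Unweighted
fits are maximum likelihood with Wald intervals; weighted fits maximise
the pseudo-likelihood (weights as frequency weights) and report a
design-based sandwich covariance: bread = inverse weighted Fisher
information, meat = stratified between-PSU covariance of the per-PSU
score totals. (Quasi-)separation is detected by non-convergence or
runaway coefficients and rescued by an L2-penalized refit that reports
point estimates only, with a warning and a `separation` flag. No
further covariates (physical activity, SES) are included: the models
exist to validate the cutoff, not to explain variance. P-values below
1e-4 display as "<0.0001".

## The synthetic-cohort generator

The generator emulates the structure of a large stratified, clustered
young-adult health survey. Defaults: 4 strata (population shares
0.4/0.3/0.2/0.1 but equal sample allocations — unequal base weights),
8 PSUs per stratum × 500 participants (16 000 sampled), one race group
oversampled 2× (its records carry half weights) and shifted +0.25 on
the latent scale, and 6 % independent per-field missingness across the
11 analysis fields, leaving ~8 000 complete cases — mirroring a
complete-case analysis that loses roughly half its respondents.

Every biomarker is driven by one latent adiposity score
Z = stratum offset + race shift + PSU effect (sd 0.15) + N(0, 1):

* height ~ N(177.6, 7.0) cm men / N(163.2, 6.5) cm women;
* waist = r_s·height + k_s·exp(U), U = λ_s Z + ν_s ε — the lognormal
  term makes WHtR right-skewed (mean ≈ 0.580 > median ≈ 0.559, as in
  adult cohorts);
* SBP/DBP (correlated noise) and HbA1c are linear in Z; TG and HDL are
  latent continuous values released as decile ranks against *weighted*
  within-sex quantile thresholds (the agency's released ranks represent
  the population, so design-weighted estimators remain unbiased even
  under heavy oversampling);
* per-sex multipliers on the slopes let component coupling differ by
  sex.

Defaults were calibrated once, by simulation, to sit near a reference
young-adult cohort's margins: MetS ≈ 23 % overall (≈ 28 % men / ≈ 20 %
women), mean WHtR ≈ 0.580, high waist ≈ 41 % men / ≈ 67 % women,
hypertension ≈ 20 %, hyperglycemia ≈ 34 %; the decile rules fix the
lipid components exactly. The calibration is frozen in
`SimulationConfig` and not re-tuned per run.

**Ground truth.** `compute_ground_truth` / `oracle_optimal_cutoff` draw
≥ 10⁶ individuals from the *population* implied by the config (strata
at population shares, untilted race mixture, PSU effects integrated
out), classify MetS with population quantile thresholds for the lipid
deciles, and brute-force the Youden optimum on a 0.001 grid spanning
the 0.1–99.9 percentile range of WHtR; prevalence and the rank-based
AUC come from the same draw. A maximal J below 0.02 is flagged
degenerate. Two diagnostic outcome modes exist for testing only:
`independent` (MetS drawn independently of everything — the oracle must
flag degeneracy) and `threshold` (MetS ≡ WHtR > c — the oracle must
return c to grid resolution).

**Seeding.** A single integer seed spawns fixed per-stage substreams
(design, demographics, latent, biomarkers, outcome, missingness, ground
truth), so the same seed reproduces the same cohort and adding a stage
cannot perturb earlier draws.

**What the generator does not model**, and what passing tests therefore
do not show about real data: school-based sampling frames, race- or
SES-specific covariance structure, non-ignorable missingness (ours is
MCAR — the complete-vs-incomplete comparison is null by construction,
unlike real cohorts), measurement error beyond rounding, or
multi-factor dependence among components beyond the single latent
score. A notable single-factor artefact: with the female component
margins held at their targets (high waist 65 % but MetS only 20 %),
female components are necessarily nearly independent, so the female
WHtR AUC (~0.70) is lower and the male AUC (~0.87) higher than the
between-sex spread typically seen in real cohorts.

## Problem sizes used in the automated checks

Scaled to make the full suite fast while keeping every estimator in its
asymptotic regime: the default cohort (~8k complete cases) for
parameter recovery (cutoff within 0.01, AUC within 0.02 of the
Monte-Carlo truth); 1 000 random datasets of n ≤ 500 for brute-force
equivalence; 500 replicate designs of 60 PSUs × 30 for CI coverage;
100 replicates of n = 1 500 for logistic OR recovery; 10⁶ Monte-Carlo
draws for the oracle.

## Numerical choices and edge cases

Grid points are rounded to 12 decimals to avoid floating-point dust in
step arithmetic; argmax ties prefer the smallest cutoff via an epsilon
ramp; zero-denominator measures return NaN and are listed in
`undefined` rather than raising; weighted tables flag, not forbid, the
iid CI formulas; a cohort file cell that is empty, "NA" or "NaN" reads
as missing while any other non-numeric token is a hard parse error
naming the row — values are never silently zeroed.
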