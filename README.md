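# whtrcut

Derivation and validation of an optimal **waist-to-height ratio (WHtR)**
cutoff for discriminating **metabolic syndrome (MetS)** in young-adult
survey cohorts, with full support for complex sampling designs
(weights, strata, clustered primary sampling units).

## The problem

WHtR — waist circumference divided by height — outperforms BMI as a
cheap screening marker of visceral adiposity, but a screening marker is
only useful with a defensible threshold. Given a cohort with
anthropometrics and cardiometabolic measurements, this package

1. builds a modified NCEP/ATP III metabolic-syndrome construct
   (MetS = ≥3 of 5 risk factors: high waist circumference — men
   > 102 cm, women > 88 cm; blood pressure ≥ 135/≥ 85 mm Hg; HbA1c
   > 5.7 % as the glycemia proxy; high TG and low HDL defined through
   sex-specific decile-rank rules when only decile ranks of the lipid
   panel are released);
2. finds the WHtR cutoff `c*` maximizing the **Youden index**
   `J(c) = Sensitivity(c) + Specificity(c) − 1` with positivity defined
   as `WHtR > c` (strict), by exhaustive search over observed values
   (unweighted) or by a two-stage grid search — 0.50–0.60 in steps of
   0.01, then ±0.01 around the coarse argmax in steps of 0.001 —
   on design-weighted contingency tables (survey-weighted);
3. reports the full diagnostic suite (sens, spec, J, PPV, NPV, PLR,
   NLR, diagnostic OR) with confidence intervals — Wilson/log-method
   for iid counts, Taylor-linearized stratified-cluster variances for
   weighted rates — plus AUC by the Mann–Whitney statistic (DeLong CI)
   or, for weighted analyses, by product-weighted concordance of a
   survey logistic model;
4. validates a derived cutoff by covariate-adjusted logistic regression
   (indicator + race + age + smoking ± sex; design-based sandwich
   variance for weighted fits) and by re-application to an external
   cohort.

Because real cohort microdata cannot ship with the package, a
first-class synthetic-cohort generator (`whtrcut.simulate`) produces
stratified, clustered, unequal-probability survey samples with a known
population optimum (computed by a Monte-Carlo oracle), so every
estimator can be tested for parameter recovery.

## Worked example

```python
from whtrcut import (SimulationConfig, simulate_cohort,
                     complete_case_filter, classify_cohort,
                     YoudenCutpointClassifier, SurveyWeightedCutpointClassifier)

cohort, truth = simulate_cohort(SimulationConfig(seed=1))
complete, _ = complete_case_filter(cohort, ["sex", "race", "age",
    "smoking_days", "height_cm", "waist_cm", "sbp", "dbp", "hba1c_pct",
    "tg_decile", "hdl_decile"])
d = classify_cohort(complete)
x, y = d["whtr"].to_numpy(), d["mets"].astype(bool).to_numpy()

clf = YoudenCutpointClassifier().fit(x, y)
print(f"unweighted cutoff {clf.cutoff_:.4f}  J={clf.youden_j_:.3f}  "
      f"AUC={clf.auc_.value:.3f}")

wclf = SurveyWeightedCutpointClassifier().fit(
    x, y, sample_weight=d["weight"], strata=d["stratum"], psu=d["psu"])
print(f"weighted   cutoff {wclf.cutoff_:.4f}  J={wclf.youden_j_:.3f}  "
      f"AUC={wclf.auc_.value:.3f}")
print(f"population truth  {truth.true_optimal_cutoff:.4f}  "
      f"AUC={truth.true_auc:.3f}")
```

prints (seed 1, n = 8 083 complete cases):

```
unweighted cutoff 0.5742  J=0.422  AUC=0.769
weighted   cutoff 0.5740  J=0.418  AUC=0.771
population truth  0.5676  AUC=0.767
```

Both pipelines land within 0.007 of the population-optimal cutoff and
within 0.004 of the population AUC. The estimators follow scikit-learn
conventions (`fit`/`predict`/`get_params`), so they compose with
sklearn pipelines; `derive_cutoff` and `weighted_grid_search` expose the
same computations functionally and additionally return the per-cutoff
sweep tables and the full diagnostic summaries.

A command-line interface mirrors the stages:

```sh
whtrcut simulate --seed 1 --out cohort.csv --truth truth.txt
whtrcut run --cohort cohort.csv --outdir out/   # full pipeline
whtrcut derive --cohort cohort.csv --weighted --sex each --out derive.json
```

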