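# episcreen

Entropy-based screening for epistatic (non-additive) interactions in
case-control cohorts, built for dichotomized clinical/environmental
phenotype studies — canonically, bronchodilator drug response (BDR) in
pediatric asthma, where the outcome is responder status (percent change
in FEV₁ after albuterol ≥ 12%) and the predictors are binary codes for
sex, age, global African ancestry, obesity, experience of discrimination
(EOD), pre-natal smoke exposure (PSE), socioeconomic status (SES) and
NO₂ exposure.

Regression-based interaction tests are tuned to multiplicative effects
and degrade badly in small samples with sparse interaction cells
(separation, collinearity). `episcreen` implements the complementary
information-theoretic screen together with everything needed to run and
audit it:

* **Main effects** as mutual information with the class,
  MI(P; C) = H(P) + H(C) − H(P, C), in bits.
* **Pairwise information gain**
  IG(P₁; P₂; C) = MI({P₁,P₂}; C) − MI(P₁; C) − MI(P₂; C): positive
  values are synergy (epistasis), negative values redundancy.
* **Three-way information gain** with synergy-only subtraction,
  IG(P₁; P₂; P₃; C) = MI({P₁,P₂,P₃}; C) − Σ_pairs max(IG₂, 0) − Σᵢ MI(Pᵢ; C),
  which stays meaningful under strongly correlated predictors (a flag
  restores the subtract-everything variant).
* **Permutation inference**: outcome reshuffling (B = 1000 by default),
  one-sided add-one p-values (1 + #{null ≥ obs})/(B + 1), one shared
  permutation set per family, and Bonferroni familywise thresholds —
  with 8 predictors: m = 8 main effects (0.05/8 → 0.006), 28 pairs
  (0.002 / 0.004) and 56 triples (0.0009 / 0.002).
* **Confounder adjustment by local case-control (LCC) subsampling**:
  fit a pilot logistic model of the outcome on the confounders only
  (age, by default), keep each row with probability |y − p̃|, and analyse
  the subsample, in which the confounder effect cancels.
* **A regression comparison arm**: multiplicative-interaction logistic
  models adjusted for age and all lower-order terms, an LP-based
  separation detector, VIF/condition-number screening, and Firth
  bias-reduced fits (Jeffreys-prior penalised likelihood, penalised-LRT
  p-values) whenever an interaction cell has fewer than 5 observations.
* **Post-hoc interaction groups**: the 2×2 group partition of a
  significant pair, two-group proportion tests (continuity-corrected χ²
  with Fisher dispatch below 5 per cell), rank-sum tests, and
  median/IQR summaries.
* **A synthetic-cohort generator** with penetrance-table epistasis whose
  marginal (and, for triples, pairwise) effects are exactly zero at the
  stated prevalences — "pure" interactions — plus an exact enumeration
  oracle (`population_ig`) for parameter-recovery testing.
* **An epistasis network** (nodes = MI, edges = pairwise IG,
  hyperedges = three-way IG, colored by verdict) exportable as JSON,
  GraphML or DOT, and a CLI orchestrating the whole pipeline.

## Worked example

Simulate the study conditions — n = 617 with age confounding, a pure
PSE × SES interaction at the observed marginal frequencies — then
adjust, screen and compare against regression:

```python
import episcreen as ep

prev = dict(ep.TABLE1_PREVALENCES)
pen = ep.pure_interaction_penetrance(("pse", "ses_low"), prev, strength=0.8)
cohort = ep.generate_cohort(ep.CohortSpec(n=617, penetrance=[pen], seed=7))

draw = ep.lcc_subsample(cohort, seed=7)         # age-adjustment subsample
res = ep.run_screen(draw.cohort, order=2, B=999, seed=1)
print(res.head(3)[["variables", "bits", "pct", "p_value", "significance"]])

bench = ep.benchmark_models(draw.cohort, [("pse", "ses_low")])
print(bench[["variables", "min_cell", "method", "assessable", "reason"]])
```

Output:

```
cohort n = 617
after LCC adjustment n = 231 | age slope 0.039 (SE 0.053)
         variables     bits      pct  p_value significance
     pse x ses_low 0.070303 7.034932    0.001  significant
  afr_hi x eod_any 0.026470 2.648749    0.002   suggestive
age_hi x bmi_obese 0.023593 2.360843    0.006         null
       variables  min_cell method  assessable     reason
   pse x ses_low        13              False separation
```

Reading this: LCC contracted 617 participants to 231 and flattened the
age→outcome slope to 0.039 (0.7 SE from zero). The embedded PSE × SES
interaction is recovered with IG = 0.070 bits (7.0% of the class
entropy) at the smallest attainable permutation p (1/1000), clearing the
Bonferroni significance threshold of 0.002 for 28 pairwise tests — while
the same model cannot be assessed by logistic regression at all: the
rare-cell structure of the pure interaction produces quasi-complete
separation, the failure mode the entropy screen is immune to.

The same pipeline is available from the shell:

```bash
episcreen all --config config.yaml --seed 7 -B 999 --out runs/demo
```

which writes screen tables, the LCC report, the regression comparison,
post-hoc summaries, network exports and a manifest recording every seed
and threshold (rerunning with the same config is byte-identical).

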