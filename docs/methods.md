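# Methods

## Statistical model

The analysis treats a case-control phenotype C (binary responder status)
and k binary predictors P₁…Pₖ. All information quantities use base-2
logarithms, so for binary C the class entropy H(C) ≤ 1 bit bounds every
statistic: main-effect MI lies in [0, H(C)] and information gain in
[−H(C), H(C)].

Main effects are plug-in mutual information, MI(P; C) = H(P) + H(C) −
H(P, C), estimated from observed cell frequencies. Pairwise information
gain subtracts both main effects from the joint MI of the
Cartesian-coded pair; it equals the (co-)interaction information of
(P₁, P₂, C), positive for synergy and negative for redundancy. Three-way
information gain subtracts the three main effects and the three pairwise
IG terms from the joint MI of the triple, clamping each pairwise term at
zero ("synergy-only" subtraction) by default. The clamp matters when
predictors are mutually correlated: without it, a strongly redundant
pair (IG₂ ≈ −H(C)) would be *added back* into the three-way statistic
and masquerade as higher-order synergy. Both behaviours are exposed
(`clamp_synergy`), because the two written forms of the statistic in the
literature differ on exactly this point; the synergy-only rule is the
default and the one used everywhere downstream.

No small-sample bias correction is applied to the entropy estimates.
Plug-in MI/IG are biased upward by roughly (df)/(2N ln 2), but inference
is by permutation of the outcome vector, which subjects the null
distribution to the same bias; calibration tests confirm a 5%-level
rejection rate of 0.049–0.051 under the null at n = 233.

## Permutation inference

P-values are one-sided in the synergy direction with the add-one
estimator p = (1 + #{null ≥ observed})/(B + 1), which cannot return 0
and has minimum 1/(B+1) (0.001 at the default B = 1000). Ties count
against the observed statistic. One shared permutation set is drawn per
testing family — main effects, pairs, triples — so that ranking across
models within a family is free of between-model Monte-Carlo noise; the
three families carry separate Bonferroni corrections (m = 8, 28, 56 for
eight predictors; familywise 0.05 and 0.10 give the "significant" and
"suggestive" critical values, printed at one significant figure: 0.006;
0.002/0.004; 0.0009/0.002). Negative (redundant) IG is reported but
never classed significant. In sex-stratified reruns, sex is removed from
the predictor set and the stratified family sizes (m = 7, 21, 35) are
used and recorded.

## Confounder adjustment (local case-control subsampling)

A pilot logistic model of the outcome on the confounders alone (default:
continuous age) is fitted by maximum likelihood; each observation is
retained with probability |y − p̃|. In the retained subsample the
pilot-estimated confounder effect is cancelled, which a balance
diagnostic verifies by refitting outcome ~ confounders on the subsample
(slope, SE, Wald p; subsamples under 20 rows are flagged). One Bernoulli
draw is made per run — the subsample size is a random variable with
expectation Σ|yᵢ − p̃ᵢ|, not a target. Age may still appear as a
*dichotomized predictor* in the interaction screen; the adjustment and
predictor roles are independent.

## Regression comparison arm

Each screened interaction is also fitted as the standard multiplicative
logistic model (outcome on continuous age, all main effects, all
lower-order products, and the highest-order product). Designs are
screened before fitting:

* **Separation** — a linear-programming feasibility check over bounded
  coefficient vectors classifies designs as none / quasi / complete.
  MLE on a separated design is refused (such models are reported "not
  assessable"), since the estimates diverge.
* **Collinearity** — per-column VIFs and the condition number of the
  standardized design; flags at VIF > 10 or condition number > 30
  annotate but never drop a model, while *exact* collinearity (infinite
  VIF) makes a model not assessable.

Sparse designs (any cell of the interaction cross-classification below
5) dispatch to Firth's bias-reduced logistic regression: Newton
iteration with step-halving on the Jeffreys-penalised likelihood
ℓ*(β) = ℓ(β) + ½ log|X'WX|, score modified by the hat-diagonal term,
tolerance 1e-8, at most 50 iterations. Firth p-values are penalised
likelihood-ratio tests (profile fits with the coefficient constrained to
zero) rather than Wald, matching common bias-reduced practice; on a
saturated 2×2 design the Firth estimate equals the Haldane add-½-cell
closed form, which the test suite verifies to 1e-6 including separated
tables.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, and its
defaults are the study conditions:

* n = 617 pre-adjustment; predictor prevalences from the adjusted
  demographic margins (e.g. PSE 40/233, low SES 79/233, female 97/233);
  baseline responder prevalence 118/233.
* Age truncated-normal, mean 14, SD 3 on [8, 21] years. The age→outcome
  coefficient defaults to 0.45 log-odds/yr, calibrated analytically so
  the expected LCC subsample from n = 617 is ≈ 233 (E[kept] =
  Σ 2p̃(1−p̃)), reproducing the study's contraction.
* Predictors are independent Bernoulli draws; the dichotomized age code
  is sampled independently of the continuous age confounder
  (confounding enters through the outcome only).
* Interactions are embedded as penetrance tables on 2–3 predictors,
  combined with the age term on the logit scale. Two families are
  provided: balanced XOR/parity tables (pure at 50% prevalences) and
  centered-product tables, base + d·Π(xⱼ − qⱼ), which have exactly zero
  marginal (and pairwise, for triples) penetrance effects at *arbitrary*
  prevalences q. `population_ig` evaluates the exact information gain of
  any penetrance spec by enumerating the joint distribution, and
  `calibrate_pure_strength` inverts it to hit a target IG.
* Continuous BDR values are drawn as exponential tails on either side of
  the 12% threshold, consistent with responder status; they exist to
  exercise the post-hoc summary/plot code and are not a spirometry
  model.

What the generator does **not** emulate: predictor-predictor
correlation (questionnaire-derived exposures co-vary in real cohorts),
age→predictor confounding paths, measurement error in self-reported
exposures, and any genotype-level structure. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those real-data features.

## Numerical and design choices

* Percent-scale IG is 100·bits/H(C) ("% of class entropy explained");
  raw bits are always co-reported since the percent normalisation is a
  reporting convention (H(C) ≈ 1 for a near-balanced class, so the two
  scales nearly coincide).
* Median splits code ties as 1 (at-or-above), so an all-equal column
  becomes constant and is excluded from screens with a warning.
* The SES composite sums three 0–2 components and classes low at a
  configurable cutoff (default ≤ 1); only the component scoring and the
  low vs medium/high split are externally fixed, so the cutoff is
  recorded in the codebook. The `ses_low` column codes 1 = low SES (the
  name matches the code); the post-hoc group numbering orients SES as
  med/high explicitly.
* BDR outliers are fenced at mean ± 4 SD by default (configurable), with
  an exclusion log.
* χ² tests on 2×2 tables use the continuity (Yates) correction
  throughout — the convention validated by reproducing all six printed
  dichotomous demographic p-values to two decimals, where the
  uncorrected statistic disagrees.
* "Sparse bin" means any *observed* cell of the interaction
  cross-classification below 5, not expected counts.
* All randomness flows from integer seeds through `numpy` SeedSequence
  spawning; pipelines rerun byte-identically, and every output table
  records its seed, B and thresholds in the run manifest.

## Problem sizes used in validation

The validation suite runs at deliberately bounded sizes chosen as its
own design: exhaustive oracle agreement over all ~4.9×10⁷ 2×2×2 tables
with total ≤ 30; permutation calibration over 1000 null cohorts of
n = 233 at B = 199; the LCC contract at n = 20 000 with a 1 log-odds/yr
confounder over 100 draws; the Firth identity on 50 random tables; and
the power comparison over 500 replicate cohorts of n = 233.

## Known limitations

* Interaction orders above 3 and continuous (differential) entropy are
  out of scope.
* The permutation engine assumes exchangeability of outcomes under the
  null; with residual confounding after subsampling this is approximate.
* For a 2×2 pure interaction at moderate effect size, the entropy screen
  and the saturated logistic interaction test are empirically
  power-equivalent (the logistic model can represent any 2×2×2 joint
  distribution); the entropy screen's practical advantage concentrates
  where regression becomes unassessable — sparse cells, separation,
  collinearity — and in higher-order models, as the regression arm's
  diagnostics make explicit.
* Firth p-values use the penalised LRT; Wald-style Firth intervals are
  not provided.
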