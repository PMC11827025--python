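# Methods

## Scope and estimands

The package estimates group-level usual-intake distributions of
daily-consumed nutrients from at most two 24-h recalls per person, and three
derived families of quantities: cut-point adequacy prevalences, TNI/FNI
nutrient-index scores, and paired baseline-vs-enriched contrasts under a
single-food addition. Analyses are stratified by household child food
security (secure = high+marginal, insecure = low+very low on the USDA
children's 8-item scale) crossed with egg-rich diet level, six subgroups in
all. Two analytic samples are used, mirroring the study design the package
supports: a diet-only sample (ages 14–17, complete food security, ≥1
reliable recall) for intake and adequacy estimates, and a supplement-complete
(DSMQ) subsample for TNI/FNI.

## Measurement-error model

For person *i*, recall *j*, with g the Box-Cox transform with exponent λ and
shift s,

    g(R_ij + s; λ) = β₀ + β_w·weekend_ij + β_s·seq2_ij + u_i + ε_ij,
    u_i ⟂ ε_ij,  u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_ε²).

Assumptions: every modeled nutrient is consumed essentially daily (a
one-part amount model; episodic two-part modeling is out of scope); recalls
are unbiased for true intake on the transformed scale after adjusting for
weekend and recall-sequence nuisance effects; random effects and errors are
Gaussian on the transformed scale.

Fitting is survey-weighted maximum likelihood. Because each person
contributes one or two recalls, person-block marginal covariances are 1×1 or
2×2 and the profile likelihood in (σ_u, σ_ε) is evaluated in closed form per
block, with the fixed effects profiled out by weighted GLS; this hand-rolled
evaluation is exact and was chosen because no installed mixed-model routine
accepts frequency-style survey weights (the implementation reproduces
statsmodels MixedLM to ~4 decimals under equal weights, which the test suite
checks). Weights enter as one weight per person, shared by that person's
recalls, and are normalized to mean 1, so all estimates are invariant to a
common rescaling.

λ is selected on the grid {0.01, 0.05, 0.10, …, 1.00} by maximizing the
weighted profile log-likelihood plus the Jacobian term
(λ − 1)·Σ_ij w_i·ln(R_ij + s), which makes likelihoods comparable across
exponents on the original scale. The grid mirrors the bounded search used by
the standard macro implementations while keeping each inner optimization a
smooth 2-parameter problem (L-BFGS-B on (σ_u, σ_ε), moment-based starting
values: within-person variance from paired differences, between-person from
the remainder).

### Numerical choices and degenerate inputs

* **Zero intakes.** g requires positive arguments; the default shift is half
  the smallest positive observed amount (0 when all amounts are positive).
  The shift is subtracted after back-transform and results are floored at 0.
* **σ_ε lower bound.** The Gaussian likelihood is unbounded as σ_ε → 0 when
  a person's recalls coincide; σ_ε is bounded below at 1e-6 of the total SD
  and a warning is emitted when the bound binds.
* **Degenerate designs.** A singular fixed-effects design (e.g. a constant
  weekend column) falls back to the minimum-norm GLS solution. Cohorts with
  no person contributing two recalls raise a variance-decomposition error:
  σ_u and σ_ε are not separable.
* **Back-transform.** The within-person expectation E_ε[g⁻¹(·)] uses 9-point
  Gauss–Hermite quadrature; against 10⁶-draw Monte Carlo integration the
  relative error is below 0.1% for σ_ε ≤ 1 on the transformed scale at
  λ = 0.5 (checked in the suite). g⁻¹ floors at 0 where λy + 1 ≤ 0.
* **Prediction point.** Usual intake is predicted at a balanced week —
  weekend share 3/7 (weekend defined as Friday–Sunday) — and at the first
  recall (sequence effects are a nuisance of the repeat interview).
* **Monte-Carlo draws.** Default 100 pseudo-draws of u per person, each
  carrying weight w_i/100; the seed is carried in the output object. Paired
  baseline/enriched runs must share the seed (enforced), so a zero
  contribution yields exactly zero differences.

## Adequacy markers and protein thresholds

Each micronutrient uses "share below the EAR" when an EAR exists and "share
above the AI" otherwise, applied at each person's own-sex cutoff before
pooling (the packaged DRI table is sex-specific for ages 14–18; choline
carries a single pooled 475 mg AI where published values are sex-specific —
the table is editable and the pooled default is deliberate, matching the
reference-value convention of the analyses this package reproduces). Protein
uses sex-specific thresholds: DGA 46 g (girls) / 52 g (boys), TFP 55 g /
75 g; the TFP values are higher because they derive from higher-calorie
menus.

## TNI/FNI scoring

Component score = survey-weighted mean of min(100, 100·T/ref), where ref is
the person's own-sex RDA (AI when no RDA exists: potassium, choline); the
total is the unweighted mean of the eight components (calcium, magnesium,
potassium, zinc, choline, folate, vitamin C, vitamin D). The TNI adds each
person's average daily supplement dose to every pseudo-draw before scoring,
so TNI ≥ FNI componentwise whenever doses are non-negative. Truncation at
the individual (pseudo-observation) level is the default: truncating the
group-mean ratio instead would let a few very high consumers mask widespread
inadequacy. The phrase "mean intakes evaluated as a percentage (≤100%)" is
genuinely ambiguous between the two readings, so the group-mean variant is
implemented behind `cap="group_mean"` and the choice is logged per run.

## Single-food addition

The food's nutrient vector (default: 50 g whole boiled/poached egg, food
code 31103010) is added to every recall day of every person in all
subgroups, current egg consumers included; the model is then refitted and
the usual-intake machinery rerun with the same seeds. No substitution or
energy rebalancing is modeled. The packaged vector is an approximate,
synthetic stand-in for the published food-composition entry (marked so in
its filename); production analyses should supply the exact vector file.

At λ = 1 the whole pipeline is location-equivariant, so a contribution c
moves the estimated mean usual intake by exactly c (up to optimizer
termination noise, < 1e-6 relative) — a strong end-to-end correctness check
that the suite exploits. With heavy intake skew the automatic zero-intake
shift can differ between arms; the exactness check therefore uses strictly
positive intakes.

## Survey inference

Fay BRR replicate weights (default coefficient 0.3, the conventional value
for this design family) are built internally from the released
stratum/2-PSU design via Hadamard half-sample assignment; replicate counts
are powers of two ≥ n_strata + 1, so assignments are balanced and the
replicate-mean weight equals the base weight. SE² =
(1/(R(1−fay)²))·Σ_r (θ_r − θ_base)². For prevalence and score tables the
replicate estimates reweight the fitted model's pseudo-observations without
refitting the measurement-error model per replicate — a deliberate
runtime/variance trade-off that captures the sampling variability of the
weighted functional but not of the model parameters; a full-refit path is
available through the estimator interface. Degrees of freedom default to
PSUs − strata.

Pairwise group contrasts use two-sided t-tests on independent estimates;
Bonferroni thresholds divide α by pairs × outcomes per analysis family
(15 pairs × 21 nutrients → 1.59e-4; 1 pair × 18 index outcomes → 2.78e-3,
consistent with the reported "<0.0002" and "<0.003" thresholds; the exact
divisors are a documented reconstruction and are configurable). Categorical
comparisons use a first-order design-adjusted Pearson chi-square (effective
sample size N_w/deff̄, F reference with design df); the second-order
Satterthwaite correction is out of scope.

## Egg-diet classification

Food-level rule on day-1 records: case-insensitive substring exclusion
("low fat", "cholesterol free", "reduced fat", "fat-free"/"fat free")
dominates; then codes starting 2502 are primarily-egg unless the description
matches an egg-substitute or non-chicken poultry-egg pattern; then
membership in a configured ingredient-code set marks ingredient-level egg
content; otherwise the food contributes nothing. Person level: any primary
food ⇒ primarily-egg (precedence), else any ingredient food ⇒
eggs-as-ingredients, else non-egg. The packaged ingredient-code set is a
small curated stand-in — no public enumeration of ingredient-containing
codes exists — and should be overridden per study.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the package targets: a national adolescent sample (14–17 y) with
14% food-insecure split 51/32/17% across the three egg-diet levels (47/39/14
among the food-secure); nine daily-consumed nutrients with Box-Cox
exponents 0.3–0.5, group medians patterned after the reported subgroup
means (e.g. choline 217–408 mg), between- and within-person CVs of 25% and
50% (typical for daily nutrients, and giving the σ_u/σ_ε = 0.5 regime the
recovery checks assume); weekend +7% and second-recall −3% effects; 85%
second-recall completion; lognormal weights with CV 0.5 over 15 strata × 2
PSUs; 30% supplement takers at fixed daily doses. Covariate effects and SDs
are placed on the transformed scale via the delta method (sd_y ≈ cv·m^λ).

Because the generating model equals the fitted model, closed-form truths
exist: the population share of usual intakes below a cutoff is
Φ((g(cutoff) − μ_g − (3/7)β_w)/σ_u). The truth targets the same
balanced-week estimand as the predictor, so generator and estimator agree
up to sampling error (the oracle and estimator coincide trivially when the
covariate effects are zero, the regime the oracle checks use).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: systematic (energy under-reporting) recall
bias, episodic consumption with true zeros, non-Gaussian random effects,
informative weights correlated with intake, item-level HFSSM response
behavior (only the raw score distribution is simulated), and real FNDDS
food-code diversity (a dozen synthetic codes stand in). Recovery results
certify the estimation machinery, not the validity of recall data.

## Problem sizes

Test-suite and acceptance runs use 2000 persons for parameter recovery,
5000 × 100 pseudo-draws for cut-point oracle checks, 10⁶ draws for the
quadrature oracle, and 300–800 persons for invariance and pipeline checks —
sizes at which the Monte-Carlo error of each check is several times smaller
than its tolerance.

## Known limitations

* One-part model only; nutrients with many true-zero days would need the
  episodic two-part extension.
* BRR variances for model-derived quantities omit model-parameter
  variability by default (see above).
* The usual-intake model pools sexes within subgroups (matching the target
  analyses); sex enters only through cutoffs and scoring references, so
  strongly sex-divergent intakes widen σ_u rather than shifting group means.
* λ is grid-selected; adjacent grid points can tie in likelihood on finite
  samples, moving variance estimates between equivalent transform scales
  (comparisons across λ should rescale by m^Δλ, as the recovery tests do).
* The 21-nutrient analysis list of the target study enumerates 20 items
  plus protein under two recommendation systems; the packaged nutrient list
  is config-driven and this count discrepancy is documented rather than
  resolved.
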