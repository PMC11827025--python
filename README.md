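# usualintake

Usual nutrient intake, nutrient adequacy, and nutrient-index scoring for
survey dietary-recall data — with single-food ("add one egg") diet modeling
and a synthetic-cohort generator with known ground truth.

## Who this is for

Nutritional epidemiologists analyzing 24-h dietary recall surveys of the
NHANES type: at most two recall days per person, complex survey weights with
a 2-PSU-per-stratum design, and subgroups defined by household child food
security (secure vs insecure, from the USDA HFSSM children's scale) crossed
with egg-rich diet level (no eggs / eggs as ingredients / primarily egg
dishes, classified from day-1 food codes). The package estimates, per
nutrient and subgroup:

* the **usual-intake distribution** (long-run average daily intake), freed
  of day-to-day measurement error;
* the **prevalence of inadequacy** by the EAR cut-point method (share below
  the EAR, or above the AI where no EAR exists; sex-specific DGA/TFP
  thresholds for protein);
* **Total / Food Nutrient Index** (TNI/FNI) scores — equal-weight means of
  truncated percent-of-RDA(/AI) component scores for eight under-consumed
  micronutrients, with (TNI) and without (FNI) supplement doses;
* the effect of **adding one serving of a single food** (by default a 50 g
  boiled/poached egg) to every person's daily intake, under common random
  numbers so baseline and enriched estimates are directly comparable;
* **Fay BRR standard errors**, pairwise t-tests with Bonferroni control, and
  Rao-Scott design-adjusted chi-square tests.

## The model

Daily intake R_ij of person *i* on recall day *j* is modeled on a Box-Cox
scale. With g(x; λ) = (x^λ − 1)/λ,

    g(R_ij + s; λ) = β₀ + β_w·weekend_ij + β_s·seq2_ij + u_i + ε_ij,
    u_i ~ N(0, σ_u²),   ε_ij ~ N(0, σ_ε²),

a one-part ("amount") measurement-error model of the kind popularized by the
National Cancer Institute for nutrients consumed nearly every day. σ_u is
between-person variation, σ_ε within-person (day-to-day) variation, and s is
a small shift handling zero intakes. λ is selected on a grid by maximizing
the survey-weighted log-likelihood including the Box-Cox Jacobian. A
person's usual intake is the within-person expectation of the
back-transformed daily intake,

    T(u) = E_ε[ g⁻¹(μ̄ + u + ε; λ) ],   μ̄ = β₀ + (3/7)·β_w,

evaluated by 9-point Gauss–Hermite quadrature with covariates balanced to a
usual week (3 weekend days of 7) and to the first recall. A weighted
Monte-Carlo sample of T over draws of u yields means, percentiles, cut-point
prevalences, and index scores.

## Worked example

```python
import usualintake as ui
from usualintake.synthetic import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(n_persons=2000, seed=1))
persons, recalls = cohort.persons, cohort.recalls

group = "secure:primarily_egg"
pg = persons[persons["group"] == group]
rg = recalls[recalls["person_id"].isin(pg["person_id"])]
weights = pg.set_index("person_id")["weight_day1_diet"]

model = ui.fit_amount_model(rg, weights, "choline", group=group)
dist = ui.predict_usual_distribution(model, pg, n_pseudo=100, seed=1)
print(f"mean usual choline intake: {dist.mean():.1f} mg")
print(f"share above the 475 mg AI: {100*ui.proportion_above(dist, 475.0):.1f}%")

vec = ui.load_food_vector().restricted_to(["choline"])
model2 = ui.fit_amount_model(ui.add_food_to_recalls(rg, vec), weights,
                             "choline", group=group)
dist2 = ui.predict_usual_distribution(model2, pg, n_pseudo=100, seed=1)
print(f"with one egg added: mean {dist2.mean():.1f} mg, "
      f"above AI {100*ui.proportion_above(dist2, 475.0):.1f}%")
```

prints

```
mean usual choline intake: 459.1 mg
share above the 475 mg AI: 42.1%
with one egg added: mean 605.9 mg, above AI 85.2%
```

The fitted model here has λ = 0.45, σ_u = 4.51, σ_ε = 5.44 on the
transformed scale (240 persons in the subgroup). The enriched mean rises by
the egg's choline contribution (147 mg per 50 g egg), and the share of the
subgroup above the Adequate Intake roughly doubles — the quantity a
food-pattern intervention analysis reports.

The same stages run from the shell:

```
usualintake simulate --out sim --seed 1
usualintake run --simulate --seed 1 --out results/
usualintake classify-diet --persons sim/persons.csv --foods sim/foods.csv --out classified.csv
```

`run` writes characteristic shares (Table-1 style), baseline and
egg-enriched adequacy-prevalence tables (Table-2/3 style), TNI/FNI score
tables, the serialized config, a structured log with the exclusion cascade,
and a manifest. Real recall data enters through `usualintake ingest`
(delimited text or SAS transport files, with an NHANES variable-name alias
map built in).

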