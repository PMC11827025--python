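"""Synthetic cohort generator with known ground truth.

Generates person, recall-day, and food-record tables with the statistical
structure the downstream analysis assumes, so that every pipeline stage can
be exercised and verified without external survey data:

* skewed daily nutrient intakes from a Box-Cox two-level model with
  between-person (``sigma_u``) and within-person (``sigma_e``) components
  and weekend / recall-sequence effects;
* up to two recalls per person, with a configurable share of
  single-recall persons;
* six subgroups (food security x egg-rich diet) with configurable
  membership probabilities and group-specific transformed-scale means;
* day-1 food records whose codes are consistent with each person's
  assigned egg-diet level (drawn from a small packaged synthetic code list);
* lognormal survey weights with strata/PSU structure (2 PSUs per stratum)
  and Fay BRR replicate weights;
* supplement takers at fixed daily doses.

Because the generating model is the fitted model, closed-form truths are
available: :func:`true_prevalence_below` gives the exact population fraction
of usual intakes below a cutoff via the Normal CDF on the transformed scale,
the oracle for cut-point recovery tests.

Default group shares and nutrient levels emulate a national adolescent
sample (14-17 y): 14% food-insecure, split 51/32/17% across non-egg /
eggs-as-ingredients / primarily-egg diets (47/39/14% among the food-secure),
with group median intakes patterned after reported subgroup means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import hadamard

from .cohort import GROUPS, EGG_LEVELS
from .survey import ReplicateWeights
from .usual_intake import boxcox, boxcox_inverse

__all__ = [
    "NutrientTruth",
    "SimConfig",
    "SyntheticCohort",
    "make_truth",
    "default_nutrient_truths",
    "generate_cohort",
    "true_prevalence_below",
    "generate_replicate_weights",
    "write_cohort",
]


@dataclass(frozen=True)
class NutrientTruth:
    """Data-generating parameters for one nutrient (transformed scale)."""

    lambda_true: float
    mu_g: dict[str, float]  # transformed-scale mean per group
    sigma_u: float  # between-person SD
    sigma_e: float  # within-person (day-to-day) SD
    beta_weekend: float = 0.0
    beta_seq: float = 0.0

    def __post_init__(self):
        if not 0 < self.lambda_true <= 1:
            raise ValueError("lambda_true must lie in (0, 1]")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("SDs must be non-negative")


def make_truth(
    lam: float,
    medians: dict[str, float],
    cv_between: float = 0.25,
    cv_within: float = 0.5,
    weekend_pct: float = 0.07,
    seq_pct: float = -0.03,
) -> NutrientTruth:
    """Build transformed-scale truth from original-scale group medians.

    SDs are set so the implied original-scale coefficients of variation are
    roughly ``cv_between`` and ``cv_within`` at the across-group median
    level (delta method: sd_y ~= cv * m**lambda); weekend and sequence
    effects are expressed as approximate percentage shifts of daily intake.
    """
    mu_g = {g: float(boxcox(m, lam)) for g, m in medians.items()}
    m_ref = float(np.mean(list(medians.values())))
    scale = m_ref**lam
    return NutrientTruth(
        lambda_true=lam,
        mu_g=mu_g,
        sigma_u=cv_between * scale,
        sigma_e=cv_within * scale,
        beta_weekend=weekend_pct * scale,
        beta_seq=seq_pct * scale,
    )


def _medians(vals) -> dict[str, float]:
    return dict(zip(GROUPS, vals))


def default_nutrient_truths() -> dict[str, NutrientTruth]:
    """Study-condition defaults: 9 daily-consumed nutrients whose group
    medians follow the reported subgroup pattern (insecure non-egg lowest,
    secure primarily-egg highest for egg-rich nutrients)."""
    # group order: insecure non/ingr/prim, secure non/ingr/prim
    return {
        "choline": make_truth(0.4, _medians([217, 296, 350, 269, 295, 408])),
        "vitamin_d": make_truth(0.3, _medians([4.0, 4.8, 5.2, 4.6, 5.0, 6.0])),
        "calcium": make_truth(0.4, _medians([850, 1000, 990, 950, 1050, 1080])),
        "magnesium": make_truth(0.4, _medians([205, 240, 232, 228, 244, 250])),
        "potassium": make_truth(0.4, _medians([1900, 2100, 2080, 2050, 2150, 2250])),
        "zinc": make_truth(0.4, _medians([8.6, 9.8, 10.1, 9.5, 10.3, 10.8])),
        "folate": make_truth(0.4, _medians([360, 430, 425, 410, 445, 455])),
        "vitamin_c": make_truth(0.3, _medians([55, 70, 66, 67, 69, 74])),
        "protein": make_truth(0.5, _medians([70, 78, 82, 75, 80, 89])),
    }


DEFAULT_GROUP_PROBS = {
    "insecure:non_egg": 0.14 * 0.51,
    "insecure:eggs_as_ingredients": 0.14 * 0.32,
    "insecure:primarily_egg": 0.14 * 0.17,
    "secure:non_egg": 0.86 * 0.47,
    "secure:eggs_as_ingredients": 0.86 * 0.39,
    "secure:primarily_egg": 0.86 * 0.14,
}

DEFAULT_SUPPLEMENT_DOSE = {
    "calcium": 200.0,
    "magnesium": 50.0,
    "potassium": 40.0,
    "zinc": 5.5,
    "choline": 10.0,
    "folate": 200.0,
    "vitamin_c": 60.0,
    "vitamin_d": 10.0,
    "protein": 0.0,
}


@dataclass(frozen=True)
class SimConfig:
    n_persons: int = 2000
    p_second_recall: float = 0.85
    n_strata: int = 15
    psus_per_stratum: int = 2
    group_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROBS)
    )
    nutrients: dict[str, NutrientTruth] = field(default_factory=default_nutrient_truths)
    supplement_prob: float = 0.3
    supplement_dose: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPPLEMENT_DOSE)
    )
    weight_cv: float = 0.5
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_persons < 1:
            raise ValueError("n_persons must be positive")
        if not 0 <= self.p_second_recall <= 1:
            raise ValueError("p_second_recall must lie in [0, 1]")
        if self.psus_per_stratum < 2:
            raise ValueError("need at least 2 PSUs per stratum")
        if set(self.group_probs) != set(GROUPS):
            raise ValueError(f"group_probs must cover exactly the groups {GROUPS}")
        probs = np.array([self.group_probs[g] for g in GROUPS])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("group_probs must be non-negative and sum to 1")
        if np.any(probs == 0):
            raise ValueError("empty groups: every group probability must be positive")
        if not 0 <= self.supplement_prob <= 1:
            raise ValueError("supplement_prob must lie in [0, 1]")
        if self.weight_cv < 0:
            raise ValueError("weight_cv must be non-negative")
        for name, t in self.nutrients.items():
            if set(t.mu_g) != set(GROUPS):
                raise ValueError(f"nutrient {name!r}: mu_g must cover all groups")
        return self


@dataclass
class SyntheticCohort:
    persons: pd.DataFrame
    recalls: pd.DataFrame
    foods: pd.DataFrame
    truth: dict[str, NutrientTruth]
    config: SimConfig


# roles in the packaged synthetic food-code list, keyed by diet level
def _load_food_codes() -> pd.DataFrame:
    from importlib import resources

    src = resources.files("usualintake.data").joinpath("synthetic_food_codes.csv")
    with resources.as_file(src) as p:
        return pd.read_csv(p, dtype={"food_code": str})


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a cohort; identical config (incl. seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    group_idx = rng.choice(len(GROUPS), size=n, p=[config.group_probs[g] for g in GROUPS])
    group = np.array(GROUPS)[group_idx]
    fs = np.array([g.split(":")[0] for g in group])
    diet = np.array([g.split(":")[1] for g in group])

    sex = rng.choice(["female", "male"], size=n)
    age = rng.integers(14, 18, size=n)
    race = rng.choice(
        ["mexican_american", "other_hispanic", "nh_white", "nh_black", "other"],
        size=n,
        p=[0.15, 0.08, 0.55, 0.15, 0.07],
    )
    insec = fs == "insecure"
    pir = np.where(
        insec,
        rng.gamma(2.0, 0.6, size=n),
        rng.gamma(3.0, 1.0, size=n),
    ).round(2)
    snap = np.where(rng.random(n) < np.where(insec, 0.55, 0.18), "yes", "no")
    nslp = rng.choice(["0", "1-4", "5"], size=n, p=[0.3, 0.25, 0.45])
    nsbp = rng.choice(["0", "1-4", "5"], size=n, p=[0.55, 0.2, 0.25])
    bmi_p = np.where(insec, 0.26, 0.18)
    bmi = np.where(
        rng.random(n) < bmi_p,
        "obese",
        rng.choice(["underweight", "healthy", "overweight"], size=n, p=[0.04, 0.78, 0.18]),
    )

    stratum = 1 + (np.arange(n) % config.n_strata)
    psu = rng.integers(1, config.psus_per_stratum + 1, size=n)

    if config.weight_cv == 0:
        w = np.ones(n)
    else:
        sig = np.sqrt(np.log1p(config.weight_cv**2))
        w = rng.lognormal(-0.5 * sig**2, sig, size=n)
    w = w * n / w.sum()

    hfssm = np.where(
        insec,
        rng.choice([2, 3, 4, 5, 6, 7, 8], size=n, p=[0.35, 0.2, 0.15, 0.12, 0.08, 0.06, 0.04]),
        rng.choice([0, 1], size=n, p=[0.85, 0.15]),
    )

    persons = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "age_y": age,
            "sex": sex,
            "race_ethnicity": race,
            "pir": pir,
            "snap": snap,
            "nslp_freq": nslp,
            "nsbp_freq": nsbp,
            "bmi_category": bmi,
            "stratum": stratum,
            "psu": psu,
            "weight_day1_diet": w,
            "hfssm_child_affirmed": hfssm,
            "food_security": fs,
            "diet_group": diet,
            "group": group,
        }
    )
    takes_supp = rng.random(n) < config.supplement_prob
    for nutr, dose in config.supplement_dose.items():
        persons[f"supp_{nutr}"] = np.where(takes_supp, float(dose), 0.0)

    # recall days: everyone has day 1; a share has day 2
    has_day2 = rng.random(n) < config.p_second_recall
    pid_rec = np.concatenate([persons["person_id"], persons["person_id"][has_day2]])
    day = np.concatenate([np.ones(n, int), np.full(int(has_day2.sum()), 2)])
    g_rec = np.concatenate([group_idx, group_idx[has_day2]])
    weekend = rng.random(len(pid_rec)) < 3.0 / 7.0
    seq2 = (day == 2).astype(float)

    recalls = pd.DataFrame(
        {
            "person_id": pid_rec,
            "day": day,
            "weekend": weekend,
            "sequence": day,
        }
    )
    u_all = {}  # person-level random intercepts, per nutrient
    for nutr, t in config.nutrients.items():
        u = rng.normal(0.0, t.sigma_u, size=n)
        u_rec = np.concatenate([u, u[has_day2]])
        eps = rng.normal(0.0, t.sigma_e, size=len(pid_rec))
        mu = np.array([t.mu_g[g] for g in GROUPS])[g_rec]
        y = mu + t.beta_weekend * weekend + t.beta_seq * seq2 + u_rec + eps
        recalls[nutr] = boxcox_inverse(y, t.lambda_true)
        u_all[nutr] = u
    recalls = recalls.sort_values(["person_id", "day"]).reset_index(drop=True)

    foods = _generate_foods(persons, rng)
    return SyntheticCohort(
        persons=persons, recalls=recalls, foods=foods, truth=dict(config.nutrients),
        config=config,
    )


def _generate_foods(persons: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Day-1 food records consistent with each person's egg-diet label."""
    codes = _load_food_codes()
    by_role = {
        role: list(zip(sub["food_code"], sub["description"]))
        for role, sub in codes.groupby("role")
    }
    rows = []
    for pid, diet in zip(persons["person_id"], persons["diet_group"]):
        items = []
        if diet == "primarily_egg":
            items.append(by_role["primary"][rng.integers(len(by_role["primary"]))])
            n_ing = rng.integers(0, 3)
            items += [by_role["ingredient"][rng.integers(len(by_role["ingredient"]))]
                      for _ in range(n_ing)]
        elif diet == "eggs_as_ingredients":
            n_ing = 1 + rng.integers(0, 2)
            items += [by_role["ingredient"][rng.integers(len(by_role["ingredient"]))]
                      for _ in range(n_ing)]
        else:
            # non-egg persons may still report substitute/poultry-egg foods,
            # which the classifier must not count as primarily-egg
            if rng.random() < 0.1:
                items.append(by_role["substitute"][rng.integers(len(by_role["substitute"]))])
        n_plain = 1 + rng.integers(0, 3)
        for _ in range(n_plain):
            code, desc = by_role["none"][rng.integers(len(by_role["none"]))]
            if rng.random() < 0.05:
                desc = f"{desc}, reduced fat"  # exercises the global exclusion
            items.append((code, desc))
        for code, desc in items:
            rows.append((pid, 1, code, desc, float(np.round(rng.lognormal(4.5, 0.5), 1))))
    return pd.DataFrame(
        rows, columns=["person_id", "day", "food_code", "description", "grams"]
    )


def true_prevalence_below(
    config: SimConfig,
    group: str,
    nutrient: str,
    cutoff: float,
    weekend_share: float = 3.0 / 7.0,
) -> float:
    """Closed-form population fraction of usual intakes below ``cutoff``.

    On the transformed scale, a person's usual-intake location is Normal
    with mean ``mu_g + weekend_share * beta_weekend`` (covariates balanced
    to a usual week, first recall) and SD ``sigma_u``, so the prevalence is
    a Normal CDF evaluated at the transformed cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if nutrient not in config.nutrients:
        raise KeyError(f"unknown nutrient {nutrient!r}")
    t = config.nutrients[nutrient]
    if group not in t.mu_g:
        raise KeyError(f"unknown group {group!r}")
    mu = t.mu_g[group] + weekend_share * t.beta_weekend
    yc = float(boxcox(cutoff, t.lambda_true))
    if t.sigma_u == 0:
        return float(yc > mu)
    return float(stats.norm.cdf((yc - mu) / t.sigma_u))


def generate_replicate_weights(
    persons: pd.DataFrame,
    n_replicates: int | None = None,
    fay: float = 0.3,
) -> ReplicateWeights:
    """Fay BRR replicate weights from a 2-PSU-per-stratum design.

    Half-sample assignment follows the rows of a Hadamard matrix of order
    ``n_replicates`` (a power of two, at least n_strata + 1; chosen
    automatically when omitted). In each replicate one PSU per stratum has
    its weights multiplied by ``2 - fay`` and the other by ``fay``.
    """
    if not 0 <= fay < 1:
        raise ValueError("fay coefficient must lie in [0, 1)")
    design = persons[["person_id", "stratum", "psu"]].copy()
    psu_counts = design.groupby("stratum")["psu"].nunique()
    if (psu_counts != 2).any():
        bad = list(psu_counts.index[psu_counts != 2])[:5]
        raise ValueError(f"strata without exactly 2 PSUs: {bad}")
    strata = sorted(psu_counts.index)
    min_r = len(strata) + 1
    if n_replicates is None:
        n_replicates = 4
        while n_replicates < min_r:
            n_replicates *= 2
    if n_replicates & (n_replicates - 1) or n_replicates < 2:
        raise ValueError("n_replicates must be a power of two")
    if n_replicates < min_r:
        raise ValueError(
            f"n_replicates must be at least n_strata + 1 = {min_r} for balance"
        )
    h = hadamard(n_replicates)

    base = persons.set_index("person_id")["weight_day1_diet"].astype(float)
    # first (lowest-numbered) PSU in each stratum follows the +1 half-sample
    first_psu = design.groupby("stratum")["psu"].min()
    is_first = (
        design["psu"].to_numpy()
        == first_psu.reindex(design["stratum"]).to_numpy()
    )
    strat_col = {s: k + 1 for k, s in enumerate(strata)}  # skip the all-ones column
    cols = np.array([strat_col[s] for s in design["stratum"]])

    reps = {}
    for r in range(n_replicates):
        sign = h[r, cols]  # +1/-1 per person via their stratum
        factor = np.where((sign == 1) == is_first, 2.0 - fay, fay)
        reps[f"rep_{r}"] = base.to_numpy() * factor
    replicates = pd.DataFrame(reps, index=design["person_id"]).reindex(base.index)
    return ReplicateWeights(base=base, replicates=replicates, fay=fay)


def write_cohort(outdir, cohort: SyntheticCohort) -> dict:
    """Write persons/recalls/foods CSVs plus a key=value truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("persons", "recalls", "foods"):
        p = outdir / f"{name}.csv"
        getattr(cohort, name).to_csv(p, index=False)
        paths[name] = p
    lines = [f"seed={cohort.config.seed}"]
    for nutr, t in cohort.truth.items():
        lines.append(f"{nutr}.lambda={t.lambda_true}")
        lines.append(f"{nutr}.sigma_u={t.sigma_u}")
        lines.append(f"{nutr}.sigma_e={t.sigma_e}")
        lines.append(f"{nutr}.beta_weekend={t.beta_weekend}")
        lines.append(f"{nutr}.beta_seq={t.beta_seq}")
        for g, m in t.mu_g.items():
            lines.append(f"{nutr}.mu.{g}={m}")
    tp = outdir / "truth.txt"
    tp.write_text("\n".join(lines) + "\n")
    paths["truth"] = tp
    return paths
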