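"""End-to-end pipeline: simulate or ingest -> classify -> model -> score ->
enrich -> test, with report tables for subgroup characteristics, adequacy
prevalences (baseline and egg-enriched), and TNI/FNI index scores.

Two analytic samples are materialized, mirroring the study design: the
diet-only sample (complete food security, >=1 recall) for usual intake and
adequacy tables, and the supplement-complete (DSMQ) sample for TNI/FNI.
Every numeric output is reproducible from the serialized config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import GROUPS, build_analytic_sample, nutrient_columns, supplement_columns
from .dietary_references import DRITable, load_dri_table, protein_threshold
from .egg_addition import FoodNutrientVector, add_food_to_recalls, load_food_vector
from .egg_diet import EggClassConfig, classify_cohort
from .nutrient_index import DEFAULT_INDEX_NUTRIENTS, add_supplements, component_score, total_score
from .survey import ReplicateWeights, brr_se, design_df, rao_scott_from_microdata
from .synthetic import SimConfig, generate_cohort, generate_replicate_weights
from .usual_intake import (
    UsualIntakeDistribution,
    fit_amount_model,
    predict_usual_distribution,
)

logger = logging.getLogger("usualintake")

__all__ = [
    "RunConfig",
    "assign_groups",
    "fit_group_models",
    "group_distributions",
    "run_table1",
    "run_table2_3",
    "run_index_tables",
    "run_full",
]

TABLE1_CHARACTERISTICS = (
    "sex",
    "race_ethnicity",
    "snap",
    "nslp_freq",
    "nsbp_freq",
    "bmi_category",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulate: SimConfig | None = None
    persons_path: str | None = None
    recalls_path: str | None = None
    foods_path: str | None = None
    nutrients: tuple[str, ...] | None = None  # default: recall columns with DRI entries
    group_scheme: str = "fs_by_egg"  # or "food_security_only"
    seed: int = 0
    n_pseudo: int = 100
    n_replicates: int | None = None
    fay: float = 0.3
    egg_vector_path: str | None = None
    indices: tuple[str, ...] = ("tni", "fni")
    min_group_size: int = 50
    outdir: str = "results"
    lambda_grid: tuple[float, ...] | None = None


def assign_groups(
    persons: pd.DataFrame,
    foods: pd.DataFrame | None = None,
    scheme: str = "fs_by_egg",
    egg_config: EggClassConfig | None = None,
) -> pd.DataFrame:
    """Attach food_security, diet_group, and the analysis ``group`` column."""
    persons = persons.copy()
    if "food_security" not in persons.columns:
        persons[["food_security_category", "food_security"]] = (
            cohort_mod.score_food_security_column(persons["hfssm_child_affirmed"])
        )
    if scheme == "food_security_only":
        persons["group"] = persons["food_security"]
        return persons
    if scheme != "fs_by_egg":
        raise ValueError(f"unknown group scheme {scheme!r}")
    if "diet_group" not in persons.columns:
        if foods is None:
            raise ValueError("fs_by_egg grouping needs diet_group or a foods table")
        persons["diet_group"] = classify_cohort(persons, foods, egg_config).to_numpy()
    persons["group"] = persons["food_security"] + ":" + persons["diet_group"]
    return persons


def fit_group_models(
    persons: pd.DataFrame,
    recalls: pd.DataFrame,
    nutrients,
    min_group_size: int = 50,
    lambda_grid=None,
) -> dict:
    """Fit the amount model independently per nutrient x group.

    Returns ``{(nutrient, group): UsualIntakeModel}``; failing cells are
    skipped with a log record so one bad cell cannot abort a run.
    """
    models = {}
    for g, pg in persons.groupby("group"):
        if len(pg) < min_group_size:
            logger.warning("group %s has %d persons (< %d)", g, len(pg), min_group_size)
        rg = recalls[recalls["person_id"].isin(pg["person_id"])]
        wts = pg.set_index("person_id")["weight_day1_diet"]
        for nutr in nutrients:
            try:
                models[(nutr, g)] = fit_amount_model(
                    rg, wts, nutr, lambda_grid=lambda_grid, group=g
                )
            except Exception as exc:  # cell failure: log and continue
                logger.error("model failed for %s x %s: %s", nutr, g, exc)
    return models


def _cell_seed(seed: int, nutrient: str, group: str) -> int:
    # stable, order-independent per-cell seed for common random numbers
    h = 0
    for ch in f"{nutrient}|{group}":
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return (seed + h) % (2**31 - 1)


def group_distributions(
    models: dict,
    persons: pd.DataFrame,
    seed: int,
    n_pseudo: int = 100,
) -> dict:
    """Predict the usual-intake distribution for every fitted cell."""
    dists = {}
    for (nutr, g), model in models.items():
        pg = persons[persons["group"] == g]
        dists[(nutr, g)] = predict_usual_distribution(
            model, pg, n_pseudo=n_pseudo, seed=_cell_seed(seed, nutr, g)
        )
    return dists


# ---------------------------------------------------------------------------
# person-level collapse and BRR SEs
# ---------------------------------------------------------------------------


def _person_means(dist: UsualIntakeDistribution, values: np.ndarray) -> pd.Series:
    """Average pseudo-draw values within person (draws are equally weighted)."""
    return pd.Series(values).groupby(pd.Series(dist.person_id)).mean()


def _weighted_person_stat(person_vals: pd.Series, weights: pd.Series) -> float:
    w = weights.reindex(person_vals.index)
    return float((w * person_vals).sum() / w.sum())


def _estimate_with_se(person_vals: pd.Series, base_w: pd.Series, rw: ReplicateWeights | None):
    est = _weighted_person_stat(person_vals, base_w)
    if rw is None:
        return est, np.nan
    se = brr_se(lambda w: _weighted_person_stat(person_vals, w), rw)
    return est, se


def _marker_indicator(dist: UsualIntakeDistribution, dri: DRITable, nutrient: str):
    """Per-pseudo-observation 'beyond the adequacy marker' indicator.

    Cutoffs are sex-specific and applied at the person level; returns the
    indicator array and the marker kind.
    """
    sexes = np.asarray(dist.sex)
    kinds = set()
    ind = np.empty(len(dist.values))
    for sx in np.unique(sexes):
        m = dri.adequacy_marker(nutrient, str(sx))
        kinds.add(m.kind)
        mask = sexes == sx
        if m.kind == "below_ear":
            ind[mask] = dist.values[mask] < m.cutoff
        else:
            ind[mask] = dist.values[mask] > m.cutoff
    if len(kinds) != 1:
        raise ValueError(f"inconsistent marker kinds across sexes for {nutrient!r}")
    return ind, kinds.pop()


def _protein_indicator(dist: UsualIntakeDistribution, system: str):
    sexes = np.asarray(dist.sex)
    ind = np.empty(len(dist.values))
    for sx in np.unique(sexes):
        thr = protein_threshold(system, str(sx))
        mask = sexes == sx
        ind[mask] = dist.values[mask] < thr
    return ind


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def run_table1(
    persons: pd.DataFrame,
    rw: ReplicateWeights | None = None,
    characteristics=TABLE1_CHARACTERISTICS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted characteristic percentages by group, plus design-adjusted
    chi-square p-values per food-security panel.

    Returns ``(shares, tests)``: shares has one row per characteristic level
    x group with n, weighted percent and BRR SE; tests has one row per
    (food-security panel, characteristic).
    """
    rows = []
    groups = [g for g in GROUPS if g in set(persons["group"])] or sorted(
        persons["group"].dropna().unique()
    )
    for g in groups:
        pg = persons[persons["group"] == g]
        if len(pg) == 0:
            logger.warning("group %s empty; column omitted", g)
            continue
        wtot = pg["weight_day1_diet"].sum()
        for char in characteristics:
            if char not in pg.columns:
                continue
            for level, sub in pg.groupby(char, dropna=True):
                pid = sub["person_id"]
                pct = 100.0 * sub["weight_day1_diet"].sum() / wtot
                if rw is not None:
                    se = brr_se(
                        lambda w, pid=pid, g=g: _table1_pct(persons, w, g, pid), rw
                    )
                else:
                    se = np.nan
                rows.append(
                    {
                        "characteristic": char,
                        "level": level,
                        "group": g,
                        "n": len(sub),
                        "pct": pct,
                        "se": se,
                    }
                )
    shares = pd.DataFrame(rows)

    tests = []
    dfd = design_df(persons)
    for fs, panel in persons.groupby("food_security"):
        if panel["diet_group"].nunique() < 2:
            continue
        for char in characteristics:
            if char not in panel.columns or panel[char].nunique() < 2:
                continue
            res = rao_scott_from_microdata(
                panel.reset_index(drop=True),
                char,
                "diet_group",
                panel.reset_index(drop=True)["weight_day1_diet"],
                df_design=dfd,
            )
            tests.append(
                {"panel": fs, "characteristic": char, "F": res["F"], "p": res["p"]}
            )
    return shares, pd.DataFrame(tests)


def _table1_pct(persons: pd.DataFrame, w: pd.Series, group: str, pid) -> float:
    wg = w.reindex(persons["person_id"]).to_numpy()
    in_g = (persons["group"] == group).to_numpy()
    num = wg[in_g & persons["person_id"].isin(pid).to_numpy()].sum()
    den = wg[in_g].sum()
    return 100.0 * num / den


def run_table2_3(
    persons: pd.DataFrame,
    recalls: pd.DataFrame,
    dri: DRITable,
    nutrients,
    vector: FoodNutrientVector | None = None,
    seed: int = 0,
    n_pseudo: int = 100,
    rw: ReplicateWeights | None = None,
    lambda_grid=None,
    min_group_size: int = 50,
    include_protein: bool = True,
) -> pd.DataFrame:
    """Adequacy-prevalence table (percent beyond the marker, +/- BRR SE).

    With ``vector`` set, recalls are enriched with the food's nutrient
    contributions first (identical seeds, so a zero vector reproduces the
    baseline exactly). Protein rows use the sex-specific DGA and TFP
    thresholds; micronutrient rows use each person's own-sex EAR (below) or
    AI (above) cutoff.
    """
    dri_nutrients = [n for n in nutrients if n in dri.nutrients]
    rec = recalls
    if vector is not None:
        modeled = list(dri_nutrients) + (["protein"] if include_protein else [])
        rec = add_food_to_recalls(recalls, vector.restricted_to(modeled))
    fit_set = list(dri_nutrients)
    if include_protein and "protein" in nutrient_columns(recalls):
        fit_set.append("protein")
    models = fit_group_models(persons, rec, fit_set, min_group_size, lambda_grid)
    dists = group_distributions(models, persons, seed=seed, n_pseudo=n_pseudo)

    rows = []
    for (nutr, g), dist in sorted(dists.items()):
        pg = persons[persons["group"] == g]
        base_w = pg.set_index("person_id")["weight_day1_diet"]
        if nutr in dri_nutrients:
            ind, kind = _marker_indicator(dist, dri, nutr)
            est, se = _estimate_with_se(_person_means(dist, ind), base_w, rw)
            rows.append(
                {
                    "nutrient": nutr,
                    "group": g,
                    "marker": kind,
                    "pct": 100.0 * est,
                    "se": 100.0 * se if np.isfinite(se) else np.nan,
                    "mean_usual": dist.mean(),
                }
            )
        if nutr == "protein":
            for system in ("dga", "tfp"):
                ind = _protein_indicator(dist, system)
                est, se = _estimate_with_se(_person_means(dist, ind), base_w, rw)
                rows.append(
                    {
                        "nutrient": f"protein_{system}",
                        "group": g,
                        "marker": f"below_{system}_threshold",
                        "pct": 100.0 * est,
                        "se": 100.0 * se if np.isfinite(se) else np.nan,
                        "mean_usual": dist.mean(),
                    }
                )
    return pd.DataFrame(rows)


def run_index_tables(
    persons: pd.DataFrame,
    recalls: pd.DataFrame,
    dri: DRITable,
    seed: int = 0,
    n_pseudo: int = 100,
    rw: ReplicateWeights | None = None,
    vector: FoodNutrientVector | None = None,
    which=("tni", "fni"),
    components=DEFAULT_INDEX_NUTRIENTS,
    lambda_grid=None,
    min_group_size: int = 50,
) -> pd.DataFrame:
    """TNI/FNI component and total scores per group (+/- BRR SE).

    TNI requires complete supplement (DSMQ) information: callers should pass
    the supplement-complete analytic sample. Component scores use
    individual-level capping against the person's own-sex RDA (or AI).
    """
    which = tuple(w.lower() for w in which)
    if "tni" in which and not supplement_columns(persons):
        logger.warning("no supp_* columns; TNI outputs omitted")
        which = tuple(w for w in which if w != "tni")
    rec = recalls
    if vector is not None:
        rec = add_food_to_recalls(recalls, vector.restricted_to(components))
    models = fit_group_models(persons, rec, components, min_group_size, lambda_grid)
    dists = group_distributions(models, persons, seed=seed, n_pseudo=n_pseudo)

    rows = []
    groups = sorted({g for (_, g) in dists})
    for g in groups:
        pg = persons[persons["group"] == g]
        base_w = pg.set_index("person_id")["weight_day1_diet"]
        for index_name in which:
            comp_means = {}
            comp_person_vals = {}
            for nutr in components:
                if (nutr, g) not in dists:
                    logger.error("missing model for %s x %s; %s incomplete", nutr, g, index_name)
                    continue
                dist = dists[(nutr, g)]
                if index_name == "tni":
                    dist = add_supplements(dist, pg, nutr)
                refs = np.array(
                    [dri.scoring_reference(nutr, str(s)) for s in dist.sex]
                )
                capped = np.minimum(100.0 * dist.values / refs, 100.0)
                pv = _person_means(dist, capped)
                comp_person_vals[nutr] = pv
                est, se = _estimate_with_se(pv, base_w, rw)
                comp_means[nutr] = est
                rows.append(
                    {
                        "index": index_name.upper(),
                        "group": g,
                        "component": nutr,
                        "score": est,
                        "se": se,
                    }
                )
            if len(comp_means) == len(components):
                tot = total_score(comp_means, components)
                if rw is not None:
                    pv_tot = pd.concat(comp_person_vals, axis=1).mean(axis=1)
                    se_tot = brr_se(lambda w: _weighted_person_stat(pv_tot, w), rw)
                else:
                    se_tot = np.nan
                rows.append(
                    {
                        "index": index_name.upper(),
                        "group": g,
                        "component": "total",
                        "score": tot,
                        "se": se_tot,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_full(config: RunConfig) -> dict:
    """Execute all stages and write tables, config, log, and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_records = []

    def log(stage: str, **kw):
        rec = {"stage": stage, "t": round(time.time() - t0, 3), **kw}
        log_records.append(rec)
        logger.info("%s %s", stage, kw)

    t0 = time.time()
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        persons, recalls, foods = cohort.persons, cohort.recalls, cohort.foods
        log("simulate", n_persons=len(persons), seed=config.simulate.seed)
    else:
        tables = cohort_mod.read_tables(
            config.persons_path, config.recalls_path, config.foods_path
        )
        persons, recalls = tables["persons"], tables["recalls"]
        foods = tables.get("foods")
        log("ingest", n_persons=len(persons))

    persons = assign_groups(persons, foods, config.group_scheme)
    persons, recalls, excl = build_analytic_sample(persons, recalls)
    log("analytic_sample", **excl)

    rw = generate_replicate_weights(persons, config.n_replicates, config.fay)
    log("replicate_weights", n_replicates=rw.n_replicates, fay=rw.fay)

    dri = load_dri_table()
    nutrients = config.nutrients or tuple(
        n for n in nutrient_columns(recalls) if n in dri.nutrients or n == "protein"
    )
    vector = load_food_vector(config.egg_vector_path)

    manifest = {}

    shares, tests = run_table1(persons, rw)
    shares.to_csv(outdir / "table1_shares.csv", index=False)
    tests.to_csv(outdir / "table1_tests.csv", index=False)
    manifest["table1"] = ["table1_shares.csv", "table1_tests.csv"]
    log("table1", n_rows=len(shares))

    common = dict(
        seed=config.seed,
        n_pseudo=config.n_pseudo,
        rw=rw,
        lambda_grid=config.lambda_grid,
        min_group_size=config.min_group_size,
    )
    t2 = run_table2_3(persons, recalls, dri, nutrients, vector=None, **common)
    t2.to_csv(outdir / "table2_baseline.csv", index=False)
    manifest["table2_baseline"] = ["table2_baseline.csv"]
    log("table2", n_rows=len(t2))

    t3 = run_table2_3(persons, recalls, dri, nutrients, vector=vector, **common)
    t3.to_csv(outdir / "table3_enriched.csv", index=False)
    manifest["table3_enriched"] = ["table3_enriched.csv"]
    log("table3", n_rows=len(t3))

    # supplement-complete (DSMQ) sample for the index scores
    index_files = []
    try:
        p_dsmq, r_dsmq, excl2 = build_analytic_sample(persons, recalls, require_dsmq=True)
        log("dsmq_sample", **excl2)
        has_dsmq = len(p_dsmq) > 0
    except cohort_mod.SchemaError:
        logger.warning("no supplement columns; index tables limited to FNI")
        p_dsmq, r_dsmq, has_dsmq = persons, recalls, False
    for enriched in (False, True):
        idx = run_index_tables(
            p_dsmq,
            r_dsmq,
            dri,
            seed=config.seed,
            n_pseudo=config.n_pseudo,
            rw=rw,
            vector=vector if enriched else None,
            which=config.indices if has_dsmq else ("fni",),
            lambda_grid=config.lambda_grid,
            min_group_size=config.min_group_size,
        )
        suffix = "enriched" if enriched else "baseline"
        for index_name, sub in idx.groupby("index"):
            fname = f"index_{index_name.lower()}_{suffix}.csv"
            sub.to_csv(outdir / fname, index=False)
            index_files.append(fname)
    manifest["index_tables"] = index_files
    log("index_tables", files=index_files)

    cfg_ser = asdict(config)
    if config.simulate is not None:
        cfg_ser["simulate"] = {
            k: v for k, v in asdict(config.simulate).items() if k != "nutrients"
        }
        cfg_ser["simulate"]["nutrients"] = {
            n: asdict(t) for n, t in config.simulate.nutrients.items()
        }
    (outdir / "config.json").write_text(json.dumps(cfg_ser, indent=2, default=str))
    with open(outdir / "run_log.jsonl", "w") as fh:
        for rec in log_records:
            fh.write(json.dumps(rec, default=str) + "\n")
    manifest["config"] = ["config.json"]
    manifest["log"] = ["run_log.jsonl"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "outdir": outdir,
        "manifest": manifest,
        "table1": (shares, tests),
        "table2": t2,
        "table3": t3,
        "exclusions": excl,
    }
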