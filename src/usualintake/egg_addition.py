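"""Single-food addition ("add one egg") modeling.

Adds the nutrient vector of one daily serving of a food — by default a 50 g
whole boiled/poached egg, food code 31103010 — to every recall day of every
person, then reruns the usual-intake estimation so that enriched and
baseline estimates can be compared under common random numbers. No
substitution or energy rebalancing is modeled: the serving is a pure
addition on top of the reported diet.

The packaged default vector (``egg_50g_synthetic.csv``) is an approximate,
synthetic stand-in for the published food-composition profile of that entry;
supply your own vector file for production analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import nutrient_columns
from .dietary_references import DRITable
from .usual_intake import (
    UsualIntakeDistribution,
    fit_amount_model,
    predict_usual_distribution,
    prevalence_below,
    proportion_above,
)

__all__ = [
    "FoodNutrientVector",
    "load_food_vector",
    "add_food_to_recalls",
    "paired_summary",
    "compare_with_and_without",
]


@dataclass(frozen=True)
class FoodNutrientVector:
    """Daily nutrient contribution of one serving of a single food."""

    nutrients: dict[str, float]
    label: str = "Egg, whole, boiled or poached, 50 g"
    food_code: str = "31103010"
    amount_g: float = 50.0

    def __post_init__(self):
        if any(v < 0 for v in self.nutrients.values()):
            raise ValueError("nutrient contributions must be non-negative")

    def restricted_to(self, nutrients) -> "FoodNutrientVector":
        return FoodNutrientVector(
            nutrients={k: v for k, v in self.nutrients.items() if k in set(nutrients)},
            label=self.label,
            food_code=self.food_code,
            amount_g=self.amount_g,
        )


def load_food_vector(path: str | Path | None = None) -> FoodNutrientVector:
    """Load a (nutrient, amount, unit) vector file; defaults to the packaged
    synthetic 50 g boiled-egg stand-in."""
    if path is None:
        src = resources.files("usualintake.data").joinpath("egg_50g_synthetic.csv")
        with resources.as_file(src) as p:
            tab = pd.read_csv(p)
    else:
        tab = pd.read_csv(path)
    return FoodNutrientVector(nutrients=dict(zip(tab["nutrient"], tab["amount"].astype(float))))


def add_food_to_recalls(recalls: pd.DataFrame, vector: FoodNutrientVector) -> pd.DataFrame:
    """Return a copy of ``recalls`` with the vector added to every day.

    Raises if the vector names a nutrient absent from the recall schema.
    """
    present = set(nutrient_columns(recalls))
    missing = [n for n in vector.nutrients if n not in present]
    if missing:
        raise KeyError(f"vector nutrients absent from recall schema: {missing}")
    out = recalls.copy()
    for nutr, amt in vector.nutrients.items():
        out[nutr] = out[nutr].astype(float) + amt
    return out


def paired_summary(
    baseline: UsualIntakeDistribution,
    enriched: UsualIntakeDistribution,
    marker=None,
) -> dict:
    """Paired baseline/enriched summary computed on common random numbers."""
    if baseline.seed != enriched.seed or baseline.n_pseudo != enriched.n_pseudo:
        raise ValueError(
            "baseline and enriched distributions must share seed and n_pseudo "
            "(otherwise differences confound Monte-Carlo noise)"
        )
    out = {
        "baseline_mean": baseline.mean(),
        "enriched_mean": enriched.mean(),
        "difference": enriched.mean() - baseline.mean(),
    }
    if marker is not None:
        fn = prevalence_below if marker.kind == "below_ear" else proportion_above
        out["marker_kind"] = marker.kind
        out["baseline_prevalence"] = fn(baseline, marker.cutoff)
        out["enriched_prevalence"] = fn(enriched, marker.cutoff)
    return out


def compare_with_and_without(
    persons: pd.DataFrame,
    recalls: pd.DataFrame,
    vector: FoodNutrientVector,
    nutrients,
    seed: int,
    n_pseudo: int = 100,
    group_col: str = "group",
    lambda_grid=None,
) -> pd.DataFrame:
    """Per group x nutrient: baseline vs enriched mean usual intake.

    Both arms are fitted and predicted with identical seeds per cell
    (common random numbers), so a zero vector yields exactly zero
    differences. Returns a tidy DataFrame.
    """
    enriched_recalls = add_food_to_recalls(recalls, vector.restricted_to(nutrients))
    rows = []
    groups = sorted(persons[group_col].dropna().unique())
    for gi, g in enumerate(groups):
        pg = persons[persons[group_col] == g]
        rg_idx = recalls["person_id"].isin(pg["person_id"])
        wts = pg.set_index("person_id")["weight_day1_diet"]
        for ni, nutr in enumerate(nutrients):
            cell_seed = (seed + 1009 * gi + 31 * ni) % (2**31 - 1)
            summaries = {}
            for arm, rec in (("baseline", recalls), ("enriched", enriched_recalls)):
                model = fit_amount_model(
                    rec[rg_idx], wts, nutr, lambda_grid=lambda_grid, group=g
                )
                summaries[arm] = predict_usual_distribution(
                    model, pg, n_pseudo=n_pseudo, seed=cell_seed
                )
            s = paired_summary(summaries["baseline"], summaries["enriched"])
            rows.append({"group": g, "nutrient": nutr, **s})
    return pd.DataFrame(rows)
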