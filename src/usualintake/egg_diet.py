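"""Egg-rich diet classification from day-1 food records.

Each person is assigned one of three levels:

``primarily_egg``
    reported at least one food from the "eggs and omelets" food-code
    category (codes starting with 2502), excluding egg substitutes and
    non-chicken poultry eggs (duck, goose, quail);
``eggs_as_ingredients``
    no primarily-egg food, but at least one food from a configured set of
    codes in which egg is an ingredient (burritos, sandwiches, pastries,
    enriched breads, ...);
``non_egg``
    neither.

Foods whose descriptions contain modified-fat phrases ("low fat",
"cholesterol free", "reduced fat", "fat-free"/"fat free") are excluded from
classification entirely, since egg content of such reformulations cannot be
confirmed. A primarily-egg food always takes precedence over any number of
ingredient foods. The packaged ingredient-code set is a curated stand-in and
should be overridden with a study-specific list where available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "EggClassConfig",
    "load_default_ingredient_codes",
    "classify_food",
    "classify_person",
    "classify_cohort",
]

EGG_LEVELS = ("non_egg", "eggs_as_ingredients", "primarily_egg")


def load_default_ingredient_codes() -> frozenset[str]:
    src = resources.files("usualintake.data").joinpath("ingredient_codes.txt")
    with resources.as_file(src) as p:
        codes = [line.strip() for line in p.read_text().splitlines() if line.strip()]
    return frozenset(codes)


@dataclass(frozen=True)
class EggClassConfig:
    primary_category_prefix: str = "2502"
    primary_exclusion_patterns: tuple[str, ...] = (
        "egg substitute",
        "duck egg",
        "goose egg",
        "quail egg",
    )
    global_exclusion_patterns: tuple[str, ...] = (
        "low fat",
        "cholesterol free",
        "reduced fat",
        "fat-free",
        "fat free",
    )
    ingredient_code_set: frozenset[str] = field(
        default_factory=load_default_ingredient_codes
    )

    def __post_init__(self):
        if not self.primary_category_prefix:
            raise ValueError("primary_category_prefix must be non-empty")


def classify_food(food_code: str, description: str, config: EggClassConfig | None = None) -> str:
    """Classify one food as ``excluded``, ``primary``, ``ingredient`` or ``none``.

    Pattern matching is case-insensitive substring matching on the
    description; global exclusions dominate everything else.
    """
    config = config or EggClassConfig()
    desc = str(description).lower()
    if any(pat.lower() in desc for pat in config.global_exclusion_patterns):
        return "excluded"
    code = str(food_code)
    if code.startswith(config.primary_category_prefix):
        if any(pat.lower() in desc for pat in config.primary_exclusion_patterns):
            # not a primarily-egg dish; may still be an ingredient food
            pass
        else:
            return "primary"
    if code in config.ingredient_code_set:
        return "ingredient"
    return "none"


def classify_person(foods_day1, config: EggClassConfig | None = None) -> str:
    """Assign the person's egg-diet level from their day-1 food records.

    ``foods_day1`` is a DataFrame with ``food_code`` and ``description``
    columns (or an iterable of (code, description) pairs). A primary food
    dominates; excluded foods contribute nothing; an empty list yields
    ``non_egg`` with a warning.
    """
    config = config or EggClassConfig()
    if isinstance(foods_day1, pd.DataFrame):
        pairs = zip(foods_day1["food_code"], foods_day1["description"])
        empty = len(foods_day1) == 0
    else:
        pairs = list(foods_day1)
        empty = len(pairs) == 0
    if empty:
        warnings.warn("no day-1 foods; classifying as non_egg", RuntimeWarning, stacklevel=2)
        return "non_egg"
    any_ingredient = False
    for code, desc in pairs:
        cls = classify_food(code, desc, config)
        if cls == "primary":
            return "primarily_egg"
        if cls == "ingredient":
            any_ingredient = True
    return "eggs_as_ingredients" if any_ingredient else "non_egg"


def classify_cohort(
    persons: pd.DataFrame,
    foods: pd.DataFrame,
    config: EggClassConfig | None = None,
) -> pd.Series:
    """Egg-diet level per person (day-1 foods only), indexed like ``persons``.

    Persons without any day-1 food record are classified ``non_egg``.
    """
    config = config or EggClassConfig()
    day1 = foods[pd.to_numeric(foods["day"], errors="coerce") == 1]
    levels = {}
    for pid, grp in day1.groupby("person_id"):
        levels[pid] = classify_person(grp, config)
    out = persons["person_id"].map(levels)
    n_missing = out.isna().sum()
    if n_missing:
        warnings.warn(
            f"{n_missing} persons had no day-1 foods; classified non_egg",
            RuntimeWarning,
            stacklevel=2,
        )
    return out.fillna("non_egg").rename("diet_group")
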