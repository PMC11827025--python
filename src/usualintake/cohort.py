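"""Person/recall/food data model, food-security scoring, and analytic-sample
construction.

Tables are plain pandas DataFrames with validated canonical schemas:

``persons``
    one row per participant: demographics, survey design (stratum, PSU,
    day-1 dietary weight), the children's food-security raw score, and
    per-nutrient daily supplement doses in ``supp_<nutrient>`` columns
    (0 for non-users, NaN when supplement information is missing).
``recalls``
    one row per person-day of nutrient totals, with ``weekend`` and
    ``sequence`` covariates; (person_id, day) unique, day in {1, 2}.
``foods``
    one row per reported food on a recall day: food code, description,
    grams (used by the egg-diet classifier).

Food security uses the USDA household children's scale: the raw count of
affirmed items (0-8) maps to high / marginal / low / very low, and the
standard dichotomy combines high+marginal as "secure" and low+very low as
"insecure".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FS_CATEGORIES",
    "EGG_LEVELS",
    "GROUPS",
    "FoodSecurityStatus",
    "SchemaError",
    "score_child_food_security",
    "score_food_security_column",
    "build_analytic_sample",
    "read_tables",
    "write_tables",
    "load_nhanes_aliases",
    "supplement_columns",
]

FS_CATEGORIES = ("high", "marginal", "low", "very_low")
EGG_LEVELS = ("non_egg", "eggs_as_ingredients", "primarily_egg")
#: The six analysis subgroups: food security x egg-rich diet level.
GROUPS = tuple(
    f"{fs}:{egg}" for fs in ("insecure", "secure") for egg in EGG_LEVELS
)

#: Default raw-score thresholds of the children's scale: minimum affirmed
#: count for each category above "high".
DEFAULT_FS_THRESHOLDS = {"marginal": 1, "low": 2, "very_low": 5}

PERSON_REQUIRED = (
    "person_id",
    "age_y",
    "sex",
    "stratum",
    "psu",
    "weight_day1_diet",
    "hfssm_child_affirmed",
)
RECALL_REQUIRED = ("person_id", "day", "weekend", "sequence")
FOOD_REQUIRED = ("person_id", "day", "food_code", "description", "grams")


class SchemaError(ValueError):
    """A table failed schema validation; ``problems`` lists the offences."""

    def __init__(self, table: str, problems: list[str]):
        self.table = table
        self.problems = problems
        super().__init__(f"{table}: " + "; ".join(problems))


@dataclass(frozen=True)
class FoodSecurityStatus:
    category: str  # high | marginal | low | very_low
    binary: str  # secure | insecure


def score_child_food_security(
    affirmed: int, thresholds: dict | None = None
) -> FoodSecurityStatus:
    """Map the children's-scale raw score (0-8) to a food-security status.

    ``thresholds`` gives the minimum affirmed count for marginal, low and
    very_low; the secure/insecure dichotomy combines high+marginal vs
    low+very_low.
    """
    th = dict(DEFAULT_FS_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if not (th["marginal"] <= th["low"] <= th["very_low"]):
        raise ValueError("food-security thresholds must be non-decreasing")
    affirmed = int(affirmed)
    if not 0 <= affirmed <= 8:
        raise ValueError(f"affirmed count must be in [0, 8], got {affirmed}")
    if affirmed >= th["very_low"]:
        cat = "very_low"
    elif affirmed >= th["low"]:
        cat = "low"
    elif affirmed >= th["marginal"]:
        cat = "marginal"
    else:
        cat = "high"
    binary = "secure" if cat in ("high", "marginal") else "insecure"
    return FoodSecurityStatus(cat, binary)


def score_food_security_column(
    affirmed: pd.Series, thresholds: dict | None = None
) -> pd.DataFrame:
    """Vectorized scoring; missing raw scores yield missing statuses."""
    cats = []
    bins = []
    for v in affirmed:
        if pd.isna(v):
            cats.append(None)
            bins.append(None)
        else:
            st = score_child_food_security(int(v), thresholds)
            cats.append(st.category)
            bins.append(st.binary)
    return pd.DataFrame(
        {"food_security_category": cats, "food_security": bins}, index=affirmed.index
    )


def supplement_columns(persons: pd.DataFrame) -> list[str]:
    return [c for c in persons.columns if c.startswith("supp_")]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _numeric_nonneg(df: pd.DataFrame, cols, table: str, problems: list[str]):
    for c in cols:
        v = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[v.notna() & (v < 0)]
        for i in bad[:10]:
            problems.append(f"negative value in column {c!r} at row {i}")
        coerced = df.index[v.isna() & df[c].notna()]
        for i in coerced[:10]:
            problems.append(f"non-numeric value in column {c!r} at row {i}")


def validate_persons(persons: pd.DataFrame) -> pd.DataFrame:
    problems: list[str] = []
    missing = [c for c in PERSON_REQUIRED if c not in persons.columns]
    if missing:
        raise SchemaError("persons", [f"missing columns: {missing}"])
    if persons["person_id"].duplicated().any():
        problems.append("duplicate person_id values")
    w = pd.to_numeric(persons["weight_day1_diet"], errors="coerce")
    for i in persons.index[w.notna() & (w <= 0)][:10]:
        problems.append(f"non-positive weight at row {i}")
    age = pd.to_numeric(persons["age_y"], errors="coerce")
    for i in persons.index[age.notna() & ((age < 14) | (age > 17))][:10]:
        problems.append(f"age outside [14, 17] at row {i}")
    h = pd.to_numeric(persons["hfssm_child_affirmed"], errors="coerce")
    for i in persons.index[h.notna() & ((h < 0) | (h > 8))][:10]:
        problems.append(f"hfssm_child_affirmed outside [0, 8] at row {i}")
    _numeric_nonneg(persons, supplement_columns(persons), "persons", problems)
    if problems:
        raise SchemaError("persons", problems)
    return persons


def validate_recalls(persons: pd.DataFrame, recalls: pd.DataFrame) -> pd.DataFrame:
    problems: list[str] = []
    missing = [c for c in RECALL_REQUIRED if c not in recalls.columns]
    if missing:
        raise SchemaError("recalls", [f"missing columns: {missing}"])
    nutr = nutrient_columns(recalls)
    if not nutr:
        problems.append("no nutrient columns found")
    if recalls.duplicated(subset=["person_id", "day"]).any():
        problems.append("duplicate (person_id, day) rows")
    day = pd.to_numeric(recalls["day"], errors="coerce")
    for i in recalls.index[~day.isin([1, 2])][:10]:
        problems.append(f"day not in {{1, 2}} at row {i}")
    orphans = set(recalls["person_id"]) - set(persons["person_id"])
    if orphans:
        problems.append(f"recalls reference unknown persons: {sorted(orphans)[:5]}")
    _numeric_nonneg(recalls, nutr, "recalls", problems)
    if problems:
        raise SchemaError("recalls", problems)
    return recalls


def validate_foods(persons: pd.DataFrame, foods: pd.DataFrame) -> pd.DataFrame:
    problems: list[str] = []
    missing = [c for c in FOOD_REQUIRED if c not in foods.columns]
    if missing:
        raise SchemaError("foods", [f"missing columns: {missing}"])
    if (foods["food_code"].astype(str).str.len() == 0).any():
        problems.append("empty food_code values")
    _numeric_nonneg(foods, ["grams"], "foods", problems)
    orphans = set(foods["person_id"]) - set(persons["person_id"])
    if orphans:
        problems.append(f"foods reference unknown persons: {sorted(orphans)[:5]}")
    if problems:
        raise SchemaError("foods", problems)
    return foods


def nutrient_columns(recalls: pd.DataFrame) -> list[str]:
    return [c for c in recalls.columns if c not in RECALL_REQUIRED]


# ---------------------------------------------------------------------------
# analytic sample
# ---------------------------------------------------------------------------


def build_analytic_sample(
    persons: pd.DataFrame,
    recalls: pd.DataFrame,
    require_dsmq: bool = False,
    fs_thresholds: dict | None = None,
):
    """Apply the analytic-sample filters and return retained tables plus a log.

    Retains persons aged 14-17 with a non-missing food-security status and
    at least one recall day; with ``require_dsmq`` additionally requires
    complete supplement information (all ``supp_*`` columns non-missing).
    Filters are applied as independent predicates, so the retained set does
    not depend on their order. Returns ``(persons, recalls, exclusion_log)``.
    """
    persons = persons.copy()
    if "food_security" not in persons.columns:
        persons[["food_security_category", "food_security"]] = (
            score_food_security_column(persons["hfssm_child_affirmed"], fs_thresholds)
        )

    age = pd.to_numeric(persons["age_y"], errors="coerce")
    ok_age = age.between(14, 17)
    ok_fs = persons["food_security"].notna()
    has_recall = persons["person_id"].isin(recalls["person_id"])

    log = {
        "input_persons": int(len(persons)),
        "excluded_age": int((~ok_age).sum()),
        "excluded_missing_food_security": int((~ok_fs).sum()),
        "excluded_no_recall": int((~has_recall).sum()),
    }
    keep = ok_age & ok_fs & has_recall
    if require_dsmq:
        supp = supplement_columns(persons)
        if not supp:
            raise SchemaError(
                "persons", ["require_dsmq: no supp_* supplement columns present"]
            )
        ok_supp = persons[supp].notna().all(axis=1)
        log["excluded_incomplete_dsmq"] = int((~ok_supp).sum())
        keep &= ok_supp
    log["retained_persons"] = int(keep.sum())
    if keep.sum() == 0:
        warnings.warn("analytic sample is empty", RuntimeWarning, stacklevel=2)

    out_p = persons.loc[keep].reset_index(drop=True)
    out_r = recalls[recalls["person_id"].isin(out_p["person_id"])].reset_index(drop=True)
    log["retained_recalls"] = int(len(out_r))
    return out_p, out_r, log


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_nhanes_aliases() -> dict[str, str]:
    """Packaged NHANES variable-name to canonical-column mapping."""
    src = resources.files("usualintake.data").joinpath("nhanes_aliases.csv")
    with resources.as_file(src) as p:
        tab = pd.read_csv(p)
    return dict(zip(tab["alias"], tab["canonical"]))


def _read_one(path: Path, aliases: dict | None) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".xpt":
        df = pd.read_sas(path, format="xport")
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    if aliases:
        df = df.rename(columns=aliases)
    return df


def read_tables(
    persons_path,
    recalls_path,
    foods_path=None,
    aliases: dict | bool | None = None,
) -> dict[str, pd.DataFrame]:
    """Read and validate persons/recalls(/foods) tables.

    Delimited text (comma for .csv, tab for .tsv/.txt) or SAS transport
    (.xpt). ``aliases=True`` applies the packaged NHANES variable-name map;
    a dict supplies a custom rename.
    """
    amap = load_nhanes_aliases() if aliases is True else (aliases or None)
    persons = validate_persons(_read_one(persons_path, amap))
    recalls = validate_recalls(persons, _read_one(recalls_path, amap))
    out = {"persons": persons, "recalls": recalls}
    if foods_path is not None:
        out["foods"] = validate_foods(persons, _read_one(foods_path, amap))
    return out


def write_tables(outdir, persons: pd.DataFrame, recalls: pd.DataFrame, foods=None):
    """Write canonical tables as CSV under ``outdir``; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in {"persons": persons, "recalls": recalls, "foods": foods}.items():
        if df is None:
            continue
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
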