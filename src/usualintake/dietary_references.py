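"""Dietary Reference Intake (DRI) lookups and adequacy markers.

Houses EAR/AI/RDA reference values for adolescents aged 14-18 y (by sex)
and the sex-specific protein thresholds of the Dietary Guidelines for
Americans (DGA) and the Thrifty Food Plan (TFP). The adequacy marker for a
nutrient is "proportion below the EAR" when an EAR is established and
"proportion above the AI" otherwise (the cut-point method convention).

The packaged table ships as an editable CSV; pass a path to
:func:`load_dri_table` to override it. Some nutrients (e.g. choline) carry a
single pooled cutoff for both sexes where published DRIs are sex-specific;
see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "DRITable",
    "AdequacyMarker",
    "load_dri_table",
    "PROTEIN_THRESHOLDS",
    "protein_threshold",
]

SEXES = ("female", "male")

#: Sex-specific daily protein thresholds (g/day) for adolescents:
#: DGA minimums at the low end of the age-group calorie range, and the
#: higher TFP menu-based recommendations.
PROTEIN_THRESHOLDS = {
    ("dga", "female"): 46.0,
    ("dga", "male"): 52.0,
    ("tfp", "female"): 55.0,
    ("tfp", "male"): 75.0,
}


def protein_threshold(system: str, sex: str) -> float:
    """Protein cutoff (g/day) under a recommendation ``system`` (dga|tfp)."""
    key = (system.lower(), sex.lower())
    if key not in PROTEIN_THRESHOLDS:
        raise KeyError(f"unknown protein threshold for system={system!r}, sex={sex!r}")
    return PROTEIN_THRESHOLDS[key]


@dataclass(frozen=True)
class AdequacyMarker:
    """The cut-point marker for one nutrient and sex.

    ``kind`` is ``below_ear`` (risk = fraction of usual intakes below the
    cutoff) or ``above_ai`` (adequacy = fraction above the cutoff).
    """

    nutrient: str
    sex: str
    kind: str  # "below_ear" | "above_ai"
    cutoff: float


class DRITable:
    """Per-nutrient, per-sex reference values (EAR, AI, RDA)."""

    def __init__(self, table: pd.DataFrame):
        required = {"nutrient", "sex", "ear", "ai", "rda", "unit"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"DRI table missing columns: {sorted(missing)}")
        tab = table.copy()
        tab["nutrient"] = tab["nutrient"].astype(str)
        tab["sex"] = tab["sex"].astype(str).str.lower()
        bad_sex = set(tab["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels in DRI table: {sorted(bad_sex)}")
        no_ref = tab[tab["ear"].isna() & tab["ai"].isna()]
        if len(no_ref):
            raise ValueError(
                "nutrients with neither EAR nor AI: "
                f"{sorted(no_ref['nutrient'].unique())}"
            )
        self._tab = tab.set_index(["nutrient", "sex"]).sort_index()

    @property
    def nutrients(self) -> list[str]:
        return sorted(self._tab.index.get_level_values("nutrient").unique())

    def _row(self, nutrient: str, sex: str) -> pd.Series:
        try:
            return self._tab.loc[(nutrient, sex.lower())]
        except KeyError:
            raise KeyError(f"no DRI entry for nutrient={nutrient!r}, sex={sex!r}") from None

    def ear(self, nutrient: str, sex: str) -> float | None:
        v = self._row(nutrient, sex)["ear"]
        return None if pd.isna(v) else float(v)

    def ai(self, nutrient: str, sex: str) -> float | None:
        v = self._row(nutrient, sex)["ai"]
        return None if pd.isna(v) else float(v)

    def rda(self, nutrient: str, sex: str) -> float | None:
        v = self._row(nutrient, sex)["rda"]
        return None if pd.isna(v) else float(v)

    def unit(self, nutrient: str) -> str:
        sub = self._tab.xs(nutrient, level="nutrient")
        return str(sub["unit"].iloc[0])

    def adequacy_marker(self, nutrient: str, sex: str) -> AdequacyMarker:
        """EAR-based marker when an EAR exists, else the AI-based marker."""
        ear = self.ear(nutrient, sex)
        if ear is not None:
            return AdequacyMarker(nutrient, sex.lower(), "below_ear", ear)
        ai = self.ai(nutrient, sex)
        # table invariant guarantees at least one of EAR/AI
        return AdequacyMarker(nutrient, sex.lower(), "above_ai", ai)

    def scoring_reference(self, nutrient: str, sex: str) -> float:
        """Denominator for nutrient-index component scores: RDA, else AI."""
        rda = self.rda(nutrient, sex)
        if rda is not None:
            return rda
        ai = self.ai(nutrient, sex)
        if ai is None:
            raise KeyError(f"no RDA or AI for {nutrient!r} ({sex})")
        return ai


def load_dri_table(path: str | Path | None = None) -> DRITable:
    """Load the packaged DRI table, or a user-supplied CSV with the same schema."""
    if path is None:
        src = resources.files("usualintake.data").joinpath("dri_table.csv")
        with resources.as_file(src) as p:
            return DRITable(pd.read_csv(p))
    return DRITable(pd.read_csv(path))
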