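"""Food Nutrient Index (FNI) and Total Nutrient Index (TNI) scoring.

Both indices summarize adherence to reference intakes for eight prioritized
under-consumed micronutrients: calcium, magnesium, potassium, zinc, choline,
folate, vitamin C, and vitamin D. Each component is the usual intake
expressed as a percentage of the RDA (or AI where no RDA exists), truncated
at 100, and the total score is the unweighted mean of the components. The
FNI scores usual intake from foods and beverages alone; the TNI adds each
person's average daily supplement dose before scoring, so TNI >= FNI
componentwise whenever doses are non-negative.

Truncation is applied at the pseudo-observation (individual) level by
default, so a group cannot mask widespread inadequacy with a few very high
consumers; ``cap="group_mean"`` applies the alternative reading in which the
group mean ratio is truncated instead.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .dietary_references import DRITable
from .usual_intake import UsualIntakeDistribution

__all__ = [
    "DEFAULT_INDEX_NUTRIENTS",
    "component_score",
    "total_score",
    "add_supplements",
]

DEFAULT_INDEX_NUTRIENTS = (
    "calcium",
    "magnesium",
    "potassium",
    "zinc",
    "choline",
    "folate",
    "vitamin_c",
    "vitamin_d",
)


def _references_per_observation(dist: UsualIntakeDistribution, reference) -> np.ndarray:
    """Expand a scalar / per-sex mapping / per-observation array of references."""
    n = len(dist.values)
    if isinstance(reference, numbers.Real):
        refs = np.full(n, float(reference))
    elif isinstance(reference, dict):
        if dist.sex is None:
            raise ValueError("per-sex reference requires the distribution to carry sex")
        refs = np.array([float(reference[str(s)]) for s in dist.sex])
    else:
        refs = np.asarray(reference, dtype=float)
        if refs.shape != (n,):
            raise ValueError("per-observation reference must match distribution length")
    if np.any(refs <= 0):
        raise ValueError("references must be positive")
    return refs


def component_score(
    dist: UsualIntakeDistribution,
    reference,
    cap: str = "individual",
) -> float:
    """Component score in [0, 100]: truncated percent of the reference intake.

    ``reference`` is a scalar amount, a ``{sex: amount}`` mapping, or a
    per-observation array. ``cap="individual"`` truncates each
    pseudo-observation's ratio at 100 before the weighted average;
    ``cap="group_mean"`` truncates the weighted mean ratio instead.
    """
    refs = _references_per_observation(dist, reference)
    ratio = 100.0 * dist.values / refs
    if cap == "individual":
        return float(np.average(np.minimum(ratio, 100.0), weights=dist.weights))
    if cap == "group_mean":
        return float(min(np.average(ratio, weights=dist.weights), 100.0))
    raise ValueError(f"unknown cap mode {cap!r}")


def total_score(components: dict[str, float], expected=DEFAULT_INDEX_NUTRIENTS) -> float:
    """Unweighted mean of the configured component scores."""
    missing = [n for n in expected if n not in components]
    if missing:
        raise KeyError(f"missing component scores: {missing}")
    vals = [float(components[n]) for n in expected]
    return float(np.mean(vals))


def add_supplements(
    dist: UsualIntakeDistribution,
    persons: pd.DataFrame,
    nutrient: str,
) -> UsualIntakeDistribution:
    """Add each person's average daily supplement dose to their pseudo-draws.

    Doses come from the ``supp_<nutrient>`` column (0 for non-users);
    weights and draw structure are unchanged, so the result is directly
    comparable with the diet-only distribution under common seeds.
    """
    col = f"supp_{nutrient}"
    if col not in persons.columns:
        raise KeyError(f"persons table lacks supplement column {col!r}")
    doses = persons.set_index("person_id")[col]
    if doses.isna().any():
        raise ValueError(f"missing supplement doses in {col!r}; filter with require_dsmq")
    if (doses < 0).any():
        raise ValueError(f"negative supplement doses in {col!r}")
    per_obs = doses.reindex(dist.person_id).to_numpy(float)
    if np.isnan(per_obs).any():
        raise ValueError("distribution contains persons absent from the persons table")
    return dist.with_values(dist.values + per_obs)
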