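"""Survey-weighted inference: Fay BRR variance, pairwise t-tests with
Bonferroni control, and design-adjusted (Rao-Scott style) chi-square tests.

NHANES-like surveys release stratum/PSU design variables rather than
replicate weights; :mod:`usualintake.synthetic` constructs Fay balanced
repeated replication (BRR) weights from a 2-PSU-per-stratum design, and this
module consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicateWeights",
    "brr_se",
    "pairwise_t",
    "bonferroni_alpha",
    "design_adjusted_chisq",
    "rao_scott_from_microdata",
    "design_df",
]


@dataclass
class ReplicateWeights:
    """Base survey weights plus Fay BRR replicate weights.

    ``base`` is a Series indexed by person_id; ``replicates`` is a DataFrame
    with the same index and one column per replicate. Under Fay's method a
    half-sample's weights are multiplied by ``2 - fay`` and the complement's
    by ``fay`` (0 <= fay < 1), so no observation is ever zeroed out.
    """

    base: pd.Series
    replicates: pd.DataFrame
    fay: float

    def __post_init__(self):
        if not 0 <= self.fay < 1:
            raise ValueError("fay coefficient must lie in [0, 1)")
        if self.replicates.shape[1] < 2 or self.replicates.shape[1] % 2:
            raise ValueError("need an even number of replicates, at least 2")
        if (self.base <= 0).any() or (self.replicates <= 0).any().any():
            raise ValueError("all weights must be positive")
        if not self.base.index.equals(self.replicates.index):
            raise ValueError("base and replicate weights must share the index")

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]


def brr_se(estimator, rw: ReplicateWeights) -> float:
    """Fay BRR standard error of a weight-functional estimator.

    ``estimator`` maps a weight Series (indexed by person_id) to a scalar.
    SE^2 = (1 / (R (1-fay)^2)) * sum_r (theta_r - theta_base)^2.
    """
    theta0 = float(estimator(rw.base))
    devs = []
    for col in rw.replicates.columns:
        th = float(estimator(rw.replicates[col]))
        if not np.isfinite(th):
            raise ValueError(f"non-finite estimate under replicate {col!r}")
        devs.append(th - theta0)
    devs = np.asarray(devs)
    r = rw.n_replicates
    return float(np.sqrt(np.sum(devs**2) / (r * (1.0 - rw.fay) ** 2)))


def pairwise_t(est1: float, se1: float, est2: float, se2: float, df: float) -> dict:
    """Two-sided t-test for a difference of independent survey estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    pooled = np.sqrt(se1**2 + se2**2)
    t = (est1 - est2) / pooled
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "p": float(p), "df": float(df)}


def bonferroni_alpha(alpha: float, n_pairs: int, n_outcomes: int) -> float:
    """Bonferroni-adjusted significance threshold for a comparison family."""
    if alpha <= 0 or n_pairs < 1 or n_outcomes < 1:
        raise ValueError("alpha and counts must be positive")
    return alpha / (n_pairs * n_outcomes)


def design_df(persons: pd.DataFrame) -> int:
    """Design degrees of freedom: number of PSUs minus number of strata."""
    psus = persons.groupby("stratum")["psu"].nunique()
    return int(psus.sum() - len(psus))


def design_adjusted_chisq(table, deff: float = 1.0, df_design: float | None = None) -> dict:
    """First-order design-adjusted Pearson chi-square on a weighted table.

    The Pearson statistic is computed on the weighted cell proportions and
    scaled to the effective sample size ``N_w / deff`` (``deff`` = mean
    design effect, 1 recovers the classical statistic on the counts). The
    adjusted statistic divided by its degrees of freedom is referred to an F
    distribution with design-based denominator df (chi-square limit when
    ``df_design`` is None).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if deff <= 0:
        raise ValueError("design effect must be positive")
    total = tab.sum()
    row = tab.sum(axis=1) / total
    col = tab.sum(axis=0) / total
    if np.any(row <= 0) or np.any(col <= 0):
        raise ValueError("empty row or column margin")
    p = tab / total
    e = np.outer(row, col)
    n_eff = total / deff
    chisq = float(n_eff * np.sum((p - e) ** 2 / e))
    df1 = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    f = chisq / df1
    if df_design is None:
        pval = float(stats.chi2.sf(chisq, df1))
    else:
        if df_design < 1:
            raise ValueError("df_design must be >= 1")
        pval = float(stats.f.sf(f, df1, df_design))
    return {"F": float(f), "p": pval, "chisq": chisq, "df1": df1, "deff": float(deff)}


def rao_scott_from_microdata(
    df: pd.DataFrame,
    row_var: str,
    col_var: str,
    weights: pd.Series,
    rw: ReplicateWeights | None = None,
    df_design: float | None = None,
) -> dict:
    """Design-adjusted chi-square from person-level categorical microdata.

    When replicate weights are supplied the mean design effect is estimated
    as the average ratio of the BRR variance of each cell proportion to its
    simple-random-sampling binomial variance; otherwise deff = 1.
    """
    sub = df[[row_var, col_var]].dropna()
    w = weights.reindex(sub.index)
    tab = pd.crosstab(sub[row_var], sub[col_var], values=w, aggfunc="sum").fillna(0.0)
    deff = 1.0
    if rw is not None:
        n = len(sub)
        total = float(w.sum())
        ratios = []
        for r_val in tab.index:
            for c_val in tab.columns:
                mask = (sub[row_var] == r_val) & (sub[col_var] == c_val)
                idx = sub.index[mask]

                def cell_prop(wt, idx=idx):
                    ws = wt.reindex(sub.index)
                    return float(ws.loc[idx].sum() / ws.sum())

                p0 = float(w.loc[idx].sum() / total)
                if 0 < p0 < 1:
                    v_brr = brr_se(cell_prop, rw) ** 2
                    v_srs = p0 * (1 - p0) / n
                    if v_srs > 0:
                        ratios.append(v_brr / v_srs)
        if ratios:
            deff = max(float(np.mean(ratios)), 1e-8)
    return design_adjusted_chisq(tab.to_numpy(), deff=deff, df_design=df_design)
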