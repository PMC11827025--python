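"""Usual-intake estimation from repeated 24-h dietary recalls.

Implements a one-part ("amount") measurement-error model in the style of the
National Cancer Institute method for nutrients consumed nearly every day.
On a Box-Cox transformed scale the model for person *i*, recall *j* is

    Y_ij = beta0 + beta_w * weekend_ij + beta_s * seq2_ij + u_i + e_ij

with a person-level random intercept ``u_i ~ N(0, sigma_u^2)`` capturing
between-person variation and ``e_ij ~ N(0, sigma_e^2)`` capturing day-to-day
(within-person) variation. The transform exponent ``lambda`` is chosen on a
grid by maximizing the weighted profile log-likelihood including the Box-Cox
Jacobian. Usual intake for a person is the within-person expectation of the
back-transformed daily intake,

    T(u) = E_e[ g^{-1}(mu + u + e; lambda) ],

evaluated by 9-point Gauss-Hermite quadrature, with recall covariates
balanced to a usual week (weekend share 3/7) and to the first recall.
A weighted Monte-Carlo sample of T over draws of ``u`` forms the estimated
usual-intake distribution, from which means, percentiles, and cut-point
prevalences are taken.

Survey weights enter the likelihood as frequency-style weights (one weight
per person, shared by that person's recalls); all estimates are invariant to
rescaling all weights by a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "boxcox",
    "boxcox_inverse",
    "default_lambda_grid",
    "UsualIntakeModel",
    "UsualIntakeDistribution",
    "fit_amount_model",
    "predict_usual_distribution",
    "prevalence_below",
    "proportion_above",
    "weighted_quantile",
]

_LOG2PI = np.log(2.0 * np.pi)


def boxcox(x, lam: float):
    """Box-Cox transform: ``(x**lam - 1)/lam`` for lam != 0, ``ln x`` at lam = 0.

    Requires strictly positive ``x`` (use a shift upstream for zero intakes).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("boxcox requires strictly positive values; apply a shift first")
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def boxcox_inverse(y, lam: float):
    """Inverse Box-Cox transform, floored at 0 where ``lam*y + 1 <= 0``."""
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.exp(y)
    base = lam * y + 1.0
    out = np.where(base > 0, np.power(np.clip(base, 0.0, None), 1.0 / lam), 0.0)
    return out


def default_lambda_grid() -> np.ndarray:
    """The searched Box-Cox exponents: {0.01, 0.05, 0.10, ..., 1.00}."""
    return np.concatenate([[0.01], np.round(np.arange(0.05, 1.0001, 0.05), 2)])


@dataclass
class UsualIntakeModel:
    """Fitted amount-model parameters for one nutrient within one subgroup."""

    nutrient: str
    group: str
    lam: float
    beta0: float
    beta_weekend: float
    beta_seq: float
    sigma_u: float
    sigma_e: float
    shift: float
    n_persons: int
    n_recalls: int
    loglik: float


@dataclass
class UsualIntakeDistribution:
    """Weighted Monte-Carlo sample of usual intakes.

    One row per pseudo-draw; each person contributes ``n_pseudo`` draws, each
    carrying 1/n_pseudo of the person's survey weight. ``person_id`` and
    ``sex`` are carried along so that sex-specific cutoffs and replicate
    weights can be applied per pseudo-observation.
    """

    values: np.ndarray
    weights: np.ndarray
    person_id: np.ndarray
    sex: np.ndarray | None
    seed: int
    n_pseudo: int
    nutrient: str = ""
    group: str = ""

    def __post_init__(self):
        if len(self.values) != len(self.weights):
            raise ValueError("values and weights must have equal length")
        if len(self.values) == 0:
            raise ValueError("empty usual-intake distribution")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def mean(self) -> float:
        return float(np.average(self.values, weights=self.weights))

    def quantile(self, q) -> np.ndarray:
        return weighted_quantile(self.values, self.weights, q)

    def with_values(self, values: np.ndarray) -> "UsualIntakeDistribution":
        return UsualIntakeDistribution(
            values=np.asarray(values, dtype=float),
            weights=self.weights,
            person_id=self.person_id,
            sex=self.sex,
            seed=self.seed,
            n_pseudo=self.n_pseudo,
            nutrient=self.nutrient,
            group=self.group,
        )


def weighted_quantile(values, weights, q):
    """Weighted quantile by the inverted-CDF rule (non-decreasing in q)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile levels must lie in [0, 1]")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w) / np.sum(w)
    idx = np.searchsorted(cw, q, side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    out = v[idx]
    return out if out.size > 1 else float(out[0])


def prevalence_below(dist: UsualIntakeDistribution, cutoff: float) -> float:
    """Weighted fraction of usual intakes strictly below ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return float(np.sum(dist.weights[dist.values < cutoff]) / np.sum(dist.weights))


def proportion_above(dist: UsualIntakeDistribution, cutoff: float) -> float:
    """Weighted fraction of usual intakes strictly above ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return float(np.sum(dist.weights[dist.values > cutoff]) / np.sum(dist.weights))


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


class VarianceDecompositionError(RuntimeError):
    """Raised when within- and between-person variance are not separable."""


def _sequence_indicator(seq: pd.Series) -> np.ndarray:
    s = seq.astype(str).str.lower()
    return np.where(s.isin(["2", "second"]), 1.0, 0.0)


def _prepare_blocks(recalls: pd.DataFrame, weights: pd.Series, nutrient: str, shift: float):
    """Split recalls into 1-recall and 2-recall person blocks, sorted by person."""
    df = recalls[["person_id", "weekend", "sequence", nutrient]].copy()
    df["seq2"] = _sequence_indicator(df["sequence"])
    df["wk"] = df["weekend"].astype(float)
    df = df.sort_values(["person_id", "seq2"], kind="stable")
    counts = df.groupby("person_id", sort=True).size()
    if counts.max() > 2:
        raise ValueError("more than 2 recalls for some persons")
    w = weights.reindex(counts.index)
    if w.isna().any():
        missing = list(w.index[w.isna()])[:5]
        raise ValueError(f"no weight for persons {missing}")
    w = w.to_numpy(float)
    w = w / w.mean()  # scale invariance; stabilizes the likelihood

    r = df[nutrient].to_numpy(float)
    if np.any(r < 0):
        raise ValueError(f"negative intakes in nutrient {nutrient!r}")
    lx = np.log(r + shift)
    X = np.column_stack([np.ones(len(df)), df["wk"].to_numpy(), df["seq2"].to_numpy()])

    pid = df["person_id"].to_numpy()
    n_per = counts.reindex(pd.unique(pid)).to_numpy()
    # counts is sorted by person_id and df too, so expand person index
    starts = np.concatenate([[0], np.cumsum(counts.to_numpy())[:-1]])
    is_pair = counts.to_numpy() == 2
    i1 = starts  # first recall row per person
    i2 = starts + 1  # valid only for pairs
    return {
        "r": r,
        "logx": lx,
        "X": X,
        "w_person": w,
        "is_pair": is_pair,
        "i1": i1,
        "i2": i2[is_pair],
        "person_ids": counts.index.to_numpy(),
        "n_obs": len(df),
    }


def _profiled_negloglik(su2: float, se2: float, blocks, y: np.ndarray):
    """Weighted Gaussian -loglik with beta profiled out by GLS, plus beta."""
    X, w = blocks["X"], blocks["w_person"]
    is_pair, i1, i2 = blocks["is_pair"], blocks["i1"], blocks["i2"]
    a = su2 + se2
    c = su2
    d = a * a - c * c  # det of the 2x2 block
    if d <= 0 or a <= 0:
        return np.inf, np.zeros(3)

    i1p = i1[is_pair]
    i1s = i1[~is_pair]
    wp, ws = w[is_pair], w[~is_pair]
    X1, X2 = X[i1p], X[i2]
    y1, y2 = y[i1p], y[i2]
    Xs, ys = X[i1s], y[i1s]

    # GLS normal equations, accumulated blockwise in closed form
    A = (a / d) * (
        np.einsum("n,ni,nj->ij", wp, X1, X1) + np.einsum("n,ni,nj->ij", wp, X2, X2)
    )
    A -= (c / d) * (
        np.einsum("n,ni,nj->ij", wp, X1, X2) + np.einsum("n,ni,nj->ij", wp, X2, X1)
    )
    b = (a / d) * (X1.T @ (wp * y1) + X2.T @ (wp * y2))
    b -= (c / d) * (X1.T @ (wp * y2) + X2.T @ (wp * y1))
    if len(i1s):
        A += np.einsum("n,ni,nj->ij", ws / a, Xs, Xs)
        b += Xs.T @ (ws * ys / a)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        # degenerate design (e.g. a constant covariate): minimum-norm solution
        beta = np.linalg.pinv(A) @ b

    r1 = y1 - X1 @ beta
    r2 = y2 - X2 @ beta
    quad = np.sum(wp * (a * (r1 * r1 + r2 * r2) - 2.0 * c * r1 * r2)) / d
    logdet = np.sum(wp) * np.log(d) + 2.0 * np.sum(wp) * _LOG2PI
    if len(i1s):
        rs = ys - Xs @ beta
        quad += np.sum(ws * rs * rs) / a
        logdet += np.sum(ws) * (np.log(a) + _LOG2PI)
    return 0.5 * (logdet + quad), beta


def _fit_variances(blocks, y: np.ndarray):
    """Maximize the weighted likelihood over (sigma_u, sigma_e) for fixed lambda."""
    is_pair, i1, i2 = blocks["is_pair"], blocks["i1"], blocks["i2"]
    w = blocks["w_person"]
    if is_pair.sum() < 2:
        raise VarianceDecompositionError(
            "need at least 2 persons with 2 recalls to separate "
            "within- from between-person variance"
        )
    # moment start: within from paired differences, between from the remainder
    dpair = y[i1[is_pair]] - y[i2]
    wp = w[is_pair]
    se2_0 = max(float(np.average(dpair**2, weights=wp)) / 2.0, 1e-10)
    ybar = float(np.average(y[i1], weights=w))
    tot = float(np.average((y[i1] - ybar) ** 2, weights=w))
    su2_0 = max(tot - se2_0, 1e-3 * se2_0)

    def nll(params):
        su, se = params
        val, _ = _profiled_negloglik(su * su, se * se, blocks, y)
        return val

    # bound sigma_e away from 0 relative to the total variation: the Gaussian
    # likelihood is unbounded as sigma_e -> 0 when recalls coincide in person
    scale = np.sqrt(se2_0 + su2_0)
    se_floor = 1e-6 * scale
    res = optimize.minimize(
        nll,
        x0=np.array([np.sqrt(su2_0), max(np.sqrt(se2_0), 2 * se_floor)]),
        method="L-BFGS-B",
        bounds=[(0.0, None), (se_floor, None)],
    )
    su, se = np.abs(res.x)
    val, beta = _profiled_negloglik(su * su, se * se, blocks, y)
    if not np.isfinite(val):
        raise RuntimeError("amount-model likelihood did not evaluate at the optimum")
    if se <= 2.0 * se_floor:
        warnings.warn(
            "within-person SD at lower bound (recalls nearly identical within person)",
            RuntimeWarning,
            stacklevel=3,
        )
    return su, se, beta, -val


def fit_amount_model(
    recalls: pd.DataFrame,
    weights: pd.Series,
    nutrient: str,
    lambda_grid=None,
    shift: float | None = None,
    group: str = "",
) -> UsualIntakeModel:
    """Fit the Box-Cox random-intercept amount model for one nutrient.

    Parameters
    ----------
    recalls
        Recall-day table with columns ``person_id, weekend, sequence`` and a
        column named ``nutrient`` holding the daily amounts.
    weights
        Survey weights indexed by ``person_id`` (one per person).
    lambda_grid
        Candidate Box-Cox exponents; defaults to :func:`default_lambda_grid`.
    shift
        Positive offset added before the transform so zero intakes are in
        the transform's domain; defaults to half the smallest positive
        observed amount (0 when all amounts are positive).

    The exponent is chosen by maximizing the weighted log-likelihood
    including the Jacobian term ``(lambda - 1) * sum_ij w_i ln(R_ij + shift)``,
    so likelihoods are comparable across exponents on the original scale.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    r = recalls[nutrient].to_numpy(float)
    if shift is None:
        pos = r[r > 0]
        if len(pos) == 0:
            raise ValueError(f"all intakes of {nutrient!r} are zero")
        shift = 0.0 if np.all(r > 0) else float(pos.min()) / 2.0
    if np.any(r + shift <= 0):
        raise ValueError("intakes plus shift must be positive")

    blocks = _prepare_blocks(recalls, weights, nutrient, shift)
    # Jacobian uses the per-observation weight (its person's weight)
    w_obs = np.empty(blocks["n_obs"])
    w_obs[blocks["i1"]] = blocks["w_person"]
    w_obs[blocks["i2"]] = blocks["w_person"][blocks["is_pair"]]
    jac_base = float(np.sum(w_obs * blocks["logx"]))

    x = blocks["r"] + shift
    best = None
    for lam in lambda_grid:
        y = boxcox(x, lam) if lam != 0 else blocks["logx"]
        try:
            su, se, beta, ll_gauss = _fit_variances(blocks, y)
        except VarianceDecompositionError:
            raise  # structural: no lambda can fix a 1-recall-only design
        except RuntimeError:
            continue
        ll = ll_gauss + (lam - 1.0) * jac_base
        if best is None or ll > best[0]:
            best = (ll, lam, su, se, beta)
    if best is None:
        raise RuntimeError(f"amount model failed to converge at every lambda for {nutrient!r}")
    ll, lam, su, se, beta = best
    return UsualIntakeModel(
        nutrient=nutrient,
        group=group,
        lam=float(lam),
        beta0=float(beta[0]),
        beta_weekend=float(beta[1]),
        beta_seq=float(beta[2]),
        sigma_u=float(su),
        sigma_e=float(se),
        shift=float(shift),
        n_persons=len(blocks["person_ids"]),
        n_recalls=blocks["n_obs"],
        loglik=float(ll),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(9)


def gauss_hermite_usual(mu, sigma_e: float, lam: float, shift: float):
    """E over day-to-day error of the back-transformed intake.

    Computes ``E_e[g^{-1}(mu + e; lam)] - shift`` (floored at 0) for
    ``e ~ N(0, sigma_e^2)`` by 9-point Gauss-Hermite quadrature. ``mu`` may
    be an array (vectorized over persons and random-intercept draws).
    """
    mu = np.asarray(mu, dtype=float)
    acc = np.zeros_like(mu)
    for z, w in zip(_GH_NODES, _GH_WEIGHTS):
        acc += w * boxcox_inverse(mu + np.sqrt(2.0) * sigma_e * z, lam)
    acc /= np.sqrt(np.pi)
    return np.clip(acc - shift, 0.0, None)


def predict_usual_distribution(
    model: UsualIntakeModel,
    persons: pd.DataFrame,
    n_pseudo: int = 100,
    seed: int = 0,
    weekend_share: float = 3.0 / 7.0,
    weight_col: str = "weight_day1_diet",
) -> UsualIntakeDistribution:
    """Monte-Carlo sample of usual intakes for the persons in ``persons``.

    Each person contributes ``n_pseudo`` pseudo-draws of the random
    intercept; recall covariates are balanced to a usual week
    (``weekend_share`` weekend days, default 3/7) and to the first recall.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be >= 1")
    pid = persons["person_id"].to_numpy()
    w = persons[weight_col].to_numpy(float)
    sex = persons["sex"].to_numpy() if "sex" in persons.columns else None

    mu_bar = model.beta0 + model.beta_weekend * weekend_share
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, model.sigma_u, size=(len(pid), n_pseudo))
    t = gauss_hermite_usual(mu_bar + u, model.sigma_e, model.lam, model.shift)

    return UsualIntakeDistribution(
        values=t.ravel(),
        weights=np.repeat(w / n_pseudo, n_pseudo),
        person_id=np.repeat(pid, n_pseudo),
        sex=None if sex is None else np.repeat(sex, n_pseudo),
        seed=seed,
        n_pseudo=n_pseudo,
        nutrient=model.nutrient,
        group=model.group,
    )
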