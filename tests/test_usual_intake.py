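"""Box-Cox transform, amount-model fitting, and usual-intake prediction.

The fitter is cross-checked against statsmodels MixedLM (an independent
implementation of the same Gaussian random-intercept likelihood) under equal
weights, and the Gauss-Hermite back-transform against brute-force Monte
Carlo integration.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from usualintake.synthetic import generate_cohort
from usualintake.usual_intake import (
    UsualIntakeModel,
    VarianceDecompositionError,
    boxcox,
    boxcox_inverse,
    fit_amount_model,
    gauss_hermite_usual,
    predict_usual_distribution,
    prevalence_below,
    proportion_above,
    weighted_quantile,
)

from conftest import homogeneous_config


class TestBoxCox:
    @given(x=st.floats(0.01, 1e4), lam=st.sampled_from([0.0, 0.1, 0.4, 0.5, 1.0]))
    @settings(max_examples=200, deadline=None)
    def test_inverse_identity(self, x, lam):
        assert boxcox_inverse(boxcox(x, lam), lam) == pytest.approx(x, rel=1e-9)

    def test_lambda_one_is_shift(self):
        x = np.array([0.5, 7.3, 100.0])
        assert np.allclose(boxcox(x, 1.0), x - 1.0)

    def test_lambda_zero_is_log(self):
        assert boxcox(np.e, 0.0) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            boxcox(np.array([1.0, 0.0]), 0.5)

    def test_inverse_floors_at_zero(self):
        # lam*y + 1 <= 0 region maps to 0 intake
        assert boxcox_inverse(-10.0, 0.5) == 0.0


def test_weighted_quantile_monotone(rng):
    v = rng.normal(size=500)
    w = rng.uniform(0.1, 2.0, size=500)
    qs = np.linspace(0, 1, 21)
    out = weighted_quantile(v, w, qs)
    assert np.all(np.diff(out) >= 0)


def _sim_recalls(n, seed, sigma_u=10.0, sigma_e=20.0, mu=100.0, bw=0.0, bs=0.0,
                 p_second=0.85):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_u, n)
    rows = []
    for i in range(n):
        k = 2 if rng.random() < p_second else 1
        for j in range(k):
            wk = rng.random() < 3 / 7
            val = mu + bw * wk + bs * (j == 1) + u[i] + rng.normal(0, sigma_e)
            rows.append((i + 1, j + 1, wk, j + 1, val))
    return pd.DataFrame(rows, columns=["person_id", "day", "weekend", "sequence", "x"])


class TestFit:
    def test_matches_mixedlm_under_equal_weights(self):
        """Dual-route check against statsmodels' random-intercept ML fit."""
        import statsmodels.formula.api as smf

        rec = _sim_recalls(800, seed=3, bw=5.0, bs=-3.0)
        w = pd.Series(1.0, index=np.arange(1, 801))
        ours = fit_amount_model(rec, w, "x", lambda_grid=[1.0])
        ref = smf.mixedlm(
            "x ~ 1 + weekend + C(sequence)", rec, groups=rec["person_id"]
        ).fit(reml=False)
        assert ours.sigma_u == pytest.approx(np.sqrt(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert ours.sigma_e == pytest.approx(np.sqrt(ref.scale), rel=1e-3)
        # beta0 is on the boxcox(x, 1) = x - 1 scale
        assert ours.beta0 + 1.0 == pytest.approx(ref.params["Intercept"], abs=1e-3)
        assert ours.beta_weekend == pytest.approx(ref.params["weekend[T.True]"], abs=1e-3)

    def test_weight_scale_invariance(self):
        rec = _sim_recalls(300, seed=4)
        w = pd.Series(np.linspace(0.5, 3.0, 300), index=np.arange(1, 301))
        m1 = fit_amount_model(rec, w, "x", lambda_grid=[0.5, 1.0])
        m2 = fit_amount_model(rec, 7.0 * w, "x", lambda_grid=[0.5, 1.0])
        assert m1.lam == m2.lam
        assert m1.sigma_u == pytest.approx(m2.sigma_u, rel=1e-9)
        assert m1.sigma_e == pytest.approx(m2.sigma_e, rel=1e-9)
        assert m1.beta0 == pytest.approx(m2.beta0, rel=1e-9)

    def test_identical_recalls_hit_lower_bound_with_warning(self):
        rec = _sim_recalls(100, seed=5, sigma_e=0.0, p_second=1.0)
        w = pd.Series(1.0, index=np.arange(1, 101))
        with pytest.warns(RuntimeWarning, match="within-person"):
            m = fit_amount_model(rec, w, "x", lambda_grid=[1.0])
        assert m.sigma_e < 1e-3 * m.sigma_u

    def test_single_recall_only_not_separable(self):
        rec = _sim_recalls(100, seed=6, p_second=0.0)
        w = pd.Series(1.0, index=np.arange(1, 101))
        with pytest.raises(VarianceDecompositionError):
            fit_amount_model(rec, w, "x", lambda_grid=[1.0])

    def test_zero_intakes_get_automatic_shift(self):
        rec = _sim_recalls(200, seed=7, mu=5.0, sigma_u=2.0, sigma_e=3.0)
        rec["x"] = rec["x"].clip(lower=0.0)
        assert (rec["x"] == 0).any()
        m = fit_amount_model(rec, pd.Series(1.0, index=np.arange(1, 201)), "x")
        assert m.shift > 0


class TestQuadrature:
    @pytest.mark.parametrize("sigma_e", [0.3, 1.0])
    def test_gauss_hermite_matches_monte_carlo(self, sigma_e, rng):
        """9-point quadrature vs 1e6-draw integration of the back-transform."""
        lam, mu = 0.5, 18.0
        gh = gauss_hermite_usual(np.array([mu]), sigma_e, lam, 0.0)[0]
        eps = rng.normal(0.0, sigma_e, size=1_000_000)
        mc = boxcox_inverse(mu + eps, lam).mean()
        assert gh == pytest.approx(mc, rel=1e-3)

    def test_linear_case_collapses(self):
        # at lam=1 (and away from the floor at 0) the quadrature of a linear
        # function is exact: E[y+1]
        mu = np.array([9.0, 20.0])
        out = gauss_hermite_usual(mu, 2.0, 1.0, 0.0)
        assert np.allclose(out, mu + 1.0, atol=1e-12)


class TestPredict:
    def _model(self, **kw):
        base = dict(
            nutrient="x", group="", lam=1.0, beta0=99.0, beta_weekend=0.7,
            beta_seq=-0.5, sigma_u=10.0, sigma_e=20.0, shift=0.0,
            n_persons=10, n_recalls=20, loglik=0.0,
        )
        base.update(kw)
        return UsualIntakeModel(**base)

    def _persons(self, n=50):
        return pd.DataFrame(
            {
                "person_id": np.arange(1, n + 1),
                "sex": ["female", "male"] * (n // 2),
                "weight_day1_diet": 1.0,
            }
        )

    def test_linear_model_closed_form_mean(self):
        model = self._model(sigma_u=0.0)
        dist = predict_usual_distribution(model, self._persons(), n_pseudo=3, seed=0)
        expected = 99.0 + 0.7 * 3 / 7 + 1.0  # balanced week, back to x-scale
        assert dist.mean() == pytest.approx(expected, abs=1e-10)

    def test_zero_between_variance_gives_identical_draws(self):
        model = self._model(sigma_u=0.0, lam=0.5, beta0=18.0, sigma_e=1.0)
        dist = predict_usual_distribution(model, self._persons(), n_pseudo=5, seed=0)
        per_person = pd.Series(dist.values).groupby(pd.Series(dist.person_id)).nunique()
        assert (per_person == 1).all()

    def test_seed_reproducibility(self):
        model = self._model()
        d1 = predict_usual_distribution(model, self._persons(), n_pseudo=4, seed=11)
        d2 = predict_usual_distribution(model, self._persons(), n_pseudo=4, seed=11)
        assert np.array_equal(d1.values, d2.values)

    def test_prevalence_partition_and_limits(self):
        model = self._model()
        dist = predict_usual_distribution(model, self._persons(), n_pseudo=10, seed=2)
        c = float(np.median(dist.values))
        below = prevalence_below(dist, c)
        above = proportion_above(dist, c)
        at = np.sum(dist.weights[dist.values == c]) / np.sum(dist.weights)
        assert below + above + at == pytest.approx(1.0)
        assert prevalence_below(dist, float(dist.values.min()) / 2 + 1e-9) == 0.0


def test_location_shift_equivariance_at_lambda_one():
    """Adding c to every recall shifts mean and percentiles by exactly c.

    Intakes are kept strictly positive (small CVs) so no automatic zero-
    intake shift kicks in; the property is exact only in that regime.
    """
    cfg = homogeneous_config(1.0, 100.0, cv_between=0.05, cv_within=0.10,
                             n=600, seed=21)
    coh = generate_cohort(cfg)
    w = coh.persons.set_index("person_id")["weight_day1_diet"]
    c = 25.0
    rec2 = coh.recalls.copy()
    rec2["x"] = rec2["x"] + c
    m1 = fit_amount_model(coh.recalls, w, "x", lambda_grid=[1.0])
    m2 = fit_amount_model(rec2, w, "x", lambda_grid=[1.0])
    d1 = predict_usual_distribution(m1, coh.persons, n_pseudo=30, seed=5)
    d2 = predict_usual_distribution(m2, coh.persons, n_pseudo=30, seed=5)
    assert d2.mean() - d1.mean() == pytest.approx(c, rel=1e-6)
    q1 = d1.quantile([0.1, 0.5, 0.9])
    q2 = d2.quantile([0.1, 0.5, 0.9])
    assert np.allclose(q2 - q1, c, rtol=1e-6)
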