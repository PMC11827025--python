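"""Fay BRR variance, pairwise t-tests, Bonferroni control, Rao-Scott chi-square."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from usualintake.survey import (
    ReplicateWeights,
    bonferroni_alpha,
    brr_se,
    design_adjusted_chisq,
    design_df,
    pairwise_t,
    rao_scott_from_microdata,
)
from usualintake.synthetic import generate_replicate_weights


def _rw_two_replicates():
    idx = pd.Index([1, 2], name="person_id")
    base = pd.Series([1.0, 1.0], index=idx)
    reps = pd.DataFrame({"rep_0": [1.7, 0.3], "rep_1": [0.3, 1.7]}, index=idx)
    return ReplicateWeights(base=base, replicates=reps, fay=0.3)


class TestBrrSe:
    def test_worked_example_gives_unit_se(self):
        """theta_base=10, replicates {10.7, 9.3}, fay 0.3 -> SE exactly 1."""
        rw = _rw_two_replicates()

        def estimator(w):
            return 10.0 + (w.loc[1] - 1.0)  # 10, 10.7, 9.3

        assert brr_se(estimator, rw) == pytest.approx(1.0, abs=1e-12)

    def test_constant_estimator_zero_se(self):
        rw = _rw_two_replicates()
        assert brr_se(lambda w: 42.0, rw) == 0.0

    def test_nonfinite_replicate_named(self):
        rw = _rw_two_replicates()

        def bad(w):
            return np.nan if w.loc[1] < 1 else 1.0

        with pytest.raises(ValueError, match="rep_1"):
            brr_se(bad, rw)

    def test_weight_rescaling_invariance_for_ratio_estimators(self, rng):
        n = 40
        persons = pd.DataFrame(
            {
                "person_id": np.arange(1, n + 1),
                "stratum": np.repeat(np.arange(1, 5), 10),
                "psu": np.tile([1, 1, 1, 2, 2, 2, 1, 2, 1, 2], 4),
                "weight_day1_diet": rng.uniform(0.5, 2.0, n),
            }
        )
        vals = pd.Series(rng.normal(10, 2, n), index=persons["person_id"])

        def wmean(w):
            return float((w * vals).sum() / w.sum())

        rw1 = generate_replicate_weights(persons, n_replicates=8)
        persons2 = persons.assign(weight_day1_diet=persons["weight_day1_diet"] * 5)
        rw2 = generate_replicate_weights(persons2, n_replicates=8)
        assert brr_se(wmean, rw1) == pytest.approx(brr_se(wmean, rw2), rel=1e-12)

    def test_brr_close_to_stratified_closed_form(self, rng):
        """Weighted mean on a 2-strata equal-weight design: BRR vs textbook
        two-PSU-per-stratum variance."""
        m = 30  # persons per PSU
        psu_means = {(1, 1): 10.0, (1, 2): 12.0, (2, 1): 9.0, (2, 2): 11.5}
        rows = []
        pid = 1
        for (s, p), mu in psu_means.items():
            for _ in range(m):
                rows.append((pid, s, p, 1.0, rng.normal(mu, 1.0)))
                pid += 1
        df = pd.DataFrame(rows, columns=["person_id", "stratum", "psu", "weight_day1_diet", "y"])
        vals = df.set_index("person_id")["y"]

        def wmean(w):
            return float((w * vals).sum() / w.sum())

        rw = generate_replicate_weights(df, n_replicates=4)
        se_brr = brr_se(wmean, rw)
        # closed form: V = sum_h (ybar_h1 - ybar_h2)^2 / 4 for equal-size PSUs
        v = 0.0
        for s in (1, 2):
            m1 = vals[df.set_index("person_id")["stratum"] == s][
                df.set_index("person_id")["psu"] == 1
            ].mean()
            m2 = vals[df.set_index("person_id")["stratum"] == s][
                df.set_index("person_id")["psu"] == 2
            ].mean()
            v += (m1 - m2) ** 2 / 4.0
        se_closed = np.sqrt(v) / 2.0  # each stratum is half the sample
        assert se_brr == pytest.approx(se_closed, rel=0.15)


class TestPairwiseT:
    def test_equal_estimates(self):
        out = pairwise_t(5.0, 1.0, 5.0, 1.0, df=20)
        assert out["t"] == 0.0 and out["p"] == pytest.approx(1.0)

    def test_arithmetic(self):
        out = pairwise_t(8.0, np.sqrt(2), 5.0, np.sqrt(2), df=30)
        assert out["t"] == pytest.approx(1.5)

    def test_p_from_t_distribution(self):
        out = pairwise_t(2.0, 1.0, 0.0, 0.0 + 1e-12, df=30)
        # t ~= 2.0 at 30 df
        assert out["p"] == pytest.approx(2 * stats.t.sf(2.0, 30), rel=1e-6)
        assert out["p"] == pytest.approx(0.0546, abs=5e-4)

    def test_symmetry_under_swap(self):
        a = pairwise_t(3.0, 0.5, 1.0, 0.7, df=12)
        b = pairwise_t(1.0, 0.7, 3.0, 0.5, df=12)
        assert a["p"] == pytest.approx(b["p"])
        assert a["t"] == pytest.approx(-b["t"])

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            pairwise_t(1.0, 0.0, 2.0, 1.0, df=10)


class TestBonferroni:
    def test_identity_family(self):
        assert bonferroni_alpha(0.05, 1, 1) == 0.05

    def test_usual_intake_family(self):
        # 6 groups -> 15 pairs, 21 nutrients; threshold below the printed 0.0002
        a = bonferroni_alpha(0.05, 15, 21)
        assert a == pytest.approx(1.587e-4, rel=1e-3)
        assert a < 0.0002

    def test_index_family(self):
        # 2 groups -> 1 pair, 18 index outcomes; below the printed 0.003
        a = bonferroni_alpha(0.05, 1, 18)
        assert a == pytest.approx(2.78e-3, abs=5e-5)
        assert a < 0.003

    @given(m=st.integers(1, 40), n=st.integers(1, 40))
    @settings(max_examples=50, deadline=None)
    def test_multiplicative(self, m, n):
        assert bonferroni_alpha(0.05, m, n) == pytest.approx(
            bonferroni_alpha(0.05, m * n, 1)
        )


class TestChiSquare:
    def test_classical_limit_matches_hand_computation(self):
        out = design_adjusted_chisq([[30, 10], [10, 30]], deff=1.0)
        assert out["chisq"] == pytest.approx(20.0)
        assert out["df1"] == 1

    def test_matches_scipy_on_counts(self):
        table = [[25, 15, 10], [20, 30, 12]]
        ours = design_adjusted_chisq(table, deff=1.0)
        ref = stats.chi2_contingency(np.asarray(table), correction=False)
        assert ours["chisq"] == pytest.approx(ref.statistic)
        assert ours["p"] == pytest.approx(ref.pvalue)

    def test_independent_table_near_zero(self):
        out = design_adjusted_chisq([[20, 20], [20, 20]], deff=1.0, df_design=10)
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_deff_scales_statistic(self):
        a = design_adjusted_chisq([[30, 10], [10, 30]], deff=1.0)
        b = design_adjusted_chisq([[30, 10], [10, 30]], deff=2.0)
        assert b["chisq"] == pytest.approx(a["chisq"] / 2.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            design_adjusted_chisq([[0, 0], [10, 30]])

    def test_microdata_wrapper(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "a": rng.choice(["x", "y"], n),
                "b": rng.choice(["u", "v"], n),
            }
        )
        out = rao_scott_from_microdata(df, "a", "b", pd.Series(np.ones(n)), df_design=15)
        assert 0 <= out["p"] <= 1


def test_design_df_counts_psus_minus_strata(small_cohort):
    # 15 strata x 2 PSUs
    assert design_df(small_cohort.persons) == 15
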