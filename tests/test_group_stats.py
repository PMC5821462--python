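"""Group contrasts: ANOVA, Fisher LSD letters, chi-square, BH-FDR, Matsuda."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabosem import group_stats as gs
from metabosem.group_stats import GroupStatsError


class TestLog10Normalize:
    def test_powers_of_ten(self):
        t, back = gs.log10_normalize([1, 10, 100])
        assert np.allclose(t, [0, 1, 2])

    def test_round_trip(self):
        x = np.array([0.3, 2.5, 17.0, 900.0])
        t, back = gs.log10_normalize(x)
        assert np.allclose(back(t), x, rtol=1e-12)

    def test_zero_rejected_with_location(self):
        with pytest.raises(GroupStatsError, match=r"positions \[1\]"):
            gs.log10_normalize([1.0, 0.0, 2.0])


class TestAnova:
    def test_hand_decomposition(self):
        """g1=(1,2,3), g2=(3,4,5): SSB=6, SSW=4 -> F=6, df=(1,4), p~0.0705."""
        F, dfb, dfw, p = gs.anova_oneway([1, 2, 3, 3, 4, 5], ["a"] * 3 + ["b"] * 3)
        assert (F, dfb, dfw) == (pytest.approx(6.0), 1, 4)
        assert p == pytest.approx(0.0705, abs=5e-4)

    def test_identical_groups_f_zero(self):
        F, _, _, p = gs.anova_oneway([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_ols_regression_oracle(self):
        """F equals the overall F of a regression on group indicators."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = np.repeat([f"g{i}" for i in range(k)], rng.integers(3, 8, size=k))
            y = rng.standard_normal(len(groups)) + rng.normal(0, 1, size=k)[
                pd.Categorical(groups).codes
            ]
            X = sm.add_constant(pd.get_dummies(pd.Series(groups), drop_first=True, dtype=float))
            ols = sm.OLS(y, X).fit()
            F, dfb, dfw, p = gs.anova_oneway(y, groups)
            assert F == pytest.approx(ols.fvalue, rel=1e-9)
            assert p == pytest.approx(ols.f_pvalue, rel=1e-6, abs=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(GroupStatsError, match="fewer than 2"):
            gs.anova_oneway([1, 2, 3], ["a", "a", "b"])


class TestFisherLsd:
    def test_separated_group_gets_own_letter(self):
        """Means 0, 0.1, 5 (sd 1, n=30): the two near groups share a letter,
        the distant one stands alone ('a' goes to the largest mean)."""
        rng = np.random.default_rng(3)
        vals = np.concatenate([
            rng.normal(0, 1, 30), rng.normal(0.1, 1, 30), rng.normal(5, 1, 30)
        ])
        groups = np.repeat(["lo", "mid", "hi"], 30)
        _, letters = gs.fisher_lsd(vals, groups)
        assert letters["hi"] == "a"
        assert letters["lo"] == letters["mid"] == "b"

    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 20)
        vals = np.concatenate([base, base + 1e-3, base - 1e-3])
        _, letters = gs.fisher_lsd(vals, np.repeat(["a", "b", "c"], 20))
        assert set(letters.values()) == {"a"}

    def test_letters_consistent_with_pairwise_p(self, default_cohort):
        """Shared letter iff the merge chain keeps pairwise p >= alpha."""
        df = default_cohort.data
        vals = np.log10(df["Triglycerides"].to_numpy())
        P, letters = gs.fisher_lsd(vals, df["group"].to_numpy(), alpha=0.05)
        for a in P.index:
            for b in P.columns:
                if a == b:
                    continue
                if set(letters[a]) & set(letters[b]):
                    assert P.loc[a, b] >= 0.05

    def test_matsuda_letter_pattern_default_calibration(self, default_config):
        """At the default calibration the insulin-sensitivity contrast
        typically separates the NAFLD group while lean and obese-only groups
        stay homogeneous (a stochastic, frequency-based check)."""
        from metabosem.cohort import generate_cohort

        share_12, separate_13 = 0, 0
        n_seeds = 30
        for seed in range(n_seeds):
            df = generate_cohort(default_config, seed).data
            t = np.log10(df["Matsuda"].to_numpy())
            _, letters = gs.fisher_lsd(t, df["group"].to_numpy())
            share_12 += bool(set(letters["G1"]) & set(letters["G2"]))
            separate_13 += not (set(letters["G1"]) & set(letters["G3"]))
        assert separate_13 == n_seeds
        assert share_12 >= 0.35 * n_seeds


class TestChiSquare:
    def test_uniform_table_chi2_zero(self):
        res = gs.chi_square_independence([[10, 10], [10, 10]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t = np.array([[23, 14, 9], [59, 10, 22]])
        a = gs.chi_square_independence(t)
        b = gs.chi_square_independence(t[::-1, ::-1])
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p == pytest.approx(b.p)

    def test_low_expected_count_flagged(self):
        assert gs.chi_square_independence([[2, 3], [3, 2]]).expected_below_5

    def test_zero_margin_rejected(self):
        with pytest.raises(GroupStatsError, match="margin"):
            gs.chi_square_independence([[0, 0], [5, 5]])


class TestBhFdr:
    def test_step_up_hand_oracle(self):
        """p = (0.01, 0.02, 0.03, 0.04), m = 4: all q collapse to 0.04."""
        assert np.allclose(gs.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert gs.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_ties_share_q(self):
        q = gs.bh_fdr([0.02, 0.5, 0.02])
        assert q[0] == pytest.approx(q[2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_dominates_p(self, ps):
        q = gs.bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(GroupStatsError):
            gs.bh_fdr([0.5, 1.2])


class TestMatsuda:
    def test_flat_profile(self):
        assert gs.matsuda_index([100] * 5, [10] * 5) == pytest.approx(10.0)

    def test_insulin_scaling_law(self):
        """Insulin enters the product twice (I0 and the profile mean), so a
        4-fold insulin scaling divides the index by 4."""
        g = [90, 120, 110, 100, 95]
        i = [8, 50, 40, 30, 20]
        assert gs.matsuda_index(g, [4 * x for x in i]) == pytest.approx(
            gs.matsuda_index(g, i) / 4
        )

    def test_derived_value(self):
        """G0=90, I0=10, Gmean=120, Imean=60 -> 10000/sqrt(6.48e6) ~ 3.93."""
        g = [90, 135, 135, 120, 120]  # mean 120
        i = [10, 80, 80, 80, 50]      # mean 60
        assert gs.matsuda_index(g, i) == pytest.approx(10000 / np.sqrt(90 * 10 * 120 * 60))

    def test_wrong_length_rejected(self):
        with pytest.raises(GroupStatsError, match="5 OGTT"):
            gs.matsuda_index([100] * 4, [10] * 4)


class TestComparisonTable:
    @pytest.fixture(scope="class")
    def table_and_plan(self, default_config, default_cohort):
        plan = gs.default_variable_plan(default_config)
        return gs.build_comparison_table(default_cohort, plan), plan

    def test_anthropometric_rows_have_no_fdr(self, table_and_plan):
        table, _ = table_and_plan
        t = table.set_index("variable")
        for v in ("Age", "BMI", "Abd_circumf", "FAT", "Sex"):
            assert np.isnan(t.loc[v, "fdr_q"])
        assert t.loc["Glucose_0", "fdr_q"] >= t.loc["Glucose_0", "p"]

    def test_q_column_is_bh_of_p_column(self, table_and_plan):
        table, plan = table_and_plan
        fam = [e.variable for e in plan if e.fdr_member]
        t = table.set_index("variable")
        assert np.allclose(t.loc[fam, "fdr_q"], gs.bh_fdr(t.loc[fam, "p"].to_numpy()))

    def test_empty_fdr_family(self, default_cohort):
        plan = [gs.PlanEntry("BMI", "continuous", False, False)]
        table = gs.build_comparison_table(default_cohort, plan)
        assert table["fdr_q"].isna().all()

    def test_group_summaries_back_transformed(self, table_and_plan, default_cohort):
        table, _ = table_and_plan
        t = table.set_index("variable")
        df = default_cohort.data
        gm = 10 ** np.log10(df.loc[df.group == "G1", "CRP"]).mean()
        assert t.loc["CRP", "G1_mean"] == pytest.approx(gm)
        assert t.loc["CRP", "G1_lo"] < gm < t.loc["CRP", "G1_hi"]
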