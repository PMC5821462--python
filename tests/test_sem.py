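"""SEM engine: parser, RAM implied covariance, ML fit, standardization,
RMSEA, modification indices."""

import numpy as np
import pandas as pd
import pytest

from metabosem import sem
from metabosem.cohort import simulate_from_sem
from metabosem.models import model_text

TWO_FACTOR = "F1 =~ a1 + a2 + a3\nF2 =~ b1 + b2 + b3\nF2 ~ F1\n"


def _two_factor_params(beta=0.5, loading=0.8):
    gen = sem.parse_model(TWO_FACTOR, identification="none")
    params = {}
    for lat, ind, _ in gen.loadings:
        params[f"{lat}=~{ind}"] = loading
        params[f"{ind}~~{ind}"] = 1.0 - loading**2
    params.update({"F1~~F1": 1.0, "F2~~F2": 1.0 - beta**2, "F2~F1": beta})
    return gen, params


class TestParser:
    def test_measurement_statement(self):
        spec = sem.parse_model("F =~ x1 + x2 + x3\n")
        assert spec.latent_vars == ("F",)
        assert spec.observed_vars == ("x1", "x2", "x3")
        # first loading fixed to 1 under fix_first_loading: only 2 free loadings
        labels = sem.free_parameters(spec)
        assert "F=~x1" not in labels
        assert {"F=~x2", "F=~x3"} <= set(labels)

    def test_empty_text_rejected(self):
        with pytest.raises(sem.SemError, match="empty"):
            sem.parse_model("  \n# only a comment\n")

    def test_cycle_rejected(self):
        with pytest.raises(sem.SemError, match="cyclic"):
            sem.parse_model("y ~ x\nx ~ z\nz ~ y\n")

    def test_bad_line_reports_number(self):
        with pytest.raises(sem.SemError, match="line 2"):
            sem.parse_model("y ~ x\nnonsense line\n")

    def test_fixed_loading_syntax(self):
        spec = sem.parse_model("F =~ 1*x1 + 0.5*x2 + x3\n")
        fixed = {(l, i): f for l, i, f in spec.loadings}
        assert fixed[("F", "x1")] == 1.0
        assert fixed[("F", "x2")] == 0.5
        assert fixed[("F", "x3")] is None

    def test_model2_round_trips(self):
        spec = sem.parse_model(model_text("model2"))
        again = sem.parse_model(sem.render_model(spec))
        assert again.loadings == spec.loadings
        assert again.paths == spec.paths
        assert again.covariances == spec.covariances
        assert set(again.observed_vars) == set(spec.observed_vars)
        assert again.latent_vars == spec.latent_vars


class TestImpliedCovariance:
    def test_diagonal_model(self):
        spec = sem.parse_model("x1 ~~ 0*x2\n", identification="none")
        sig = sem.implied_covariance(spec, {"x1~~x1": 2.0, "x2~~x2": 3.0})
        assert np.allclose(sig, np.diag([2.0, 3.0]))

    def test_one_factor_analytic(self):
        spec = sem.parse_model("F =~ x1 + x2\n", identification="none")
        sig = sem.implied_covariance(
            spec, {"F=~x1": 1, "F=~x2": 1, "F~~F": 1, "x1~~x1": 0, "x2~~x2": 0}
        )
        assert np.allclose(sig, [[1, 1], [1, 1]])

    def test_single_path_analytic(self):
        """x -> y with b = 0.5, var(x) = 1, resid var(y) = 0.75 implies unit
        variances and covariance 0.5."""
        spec = sem.parse_model("y ~ x\n", identification="none")
        sig = sem.implied_covariance(spec, {"y~x": 0.5, "x~~x": 1.0, "y~~y": 0.75})
        assert spec.observed_vars == ("y", "x")
        assert np.allclose(sig, [[1.0, 0.5], [0.5, 1.0]])

    def test_exact_symmetry(self):
        gen, params = _two_factor_params()
        sig = sem.implied_covariance(gen, params)
        assert np.array_equal(sig, sig.T)


class TestFml:
    def test_zero_at_sample_covariance(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((30, 4))
        S = np.cov(A, rowvar=False)
        assert sem.fml(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_for_pd_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            A = rng.standard_normal((40, 3))
            B = rng.standard_normal((40, 3))
            S1 = np.cov(A, rowvar=False)
            S2 = np.cov(B, rowvar=False)
            assert sem.fml(S1, S2) >= -1e-12


class TestFitMl:
    def test_saturated_model_zero_chi2(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 3))
        text = "x1 ~~ x2\nx1 ~~ x3\nx2 ~~ x3\n"
        fit = sem.fit_ml(sem.parse_model(text), pd.DataFrame(X, columns=["x1", "x2", "x3"]))
        assert fit.df == 0
        assert fit.fml == pytest.approx(0.0, abs=1e-8)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-5)

    def test_single_path_equals_ols_slope(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(400)
        y = 0.7 * x + rng.standard_normal(400)
        fit = sem.fit_ml(sem.parse_model("y ~ x\n"), pd.DataFrame({"y": y, "x": x}))
        b_ols = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.estimates["y~x"] == pytest.approx(b_ols, abs=1e-6)

    def test_parameter_recovery_three_se_coverage(self):
        """Fitting data simulated from a known two-latent model recovers every
        free parameter within 3 SEs in >= 95% of replicates."""
        gen, params = _two_factor_params()
        fit_spec = sem.parse_model(TWO_FACTOR)
        # truth in the fit parameterization (first loading fixed at 1):
        # latent variance absorbs loading^2, remaining loadings are ratios = 1
        truth = {
            "F1=~a2": 1.0, "F1=~a3": 1.0, "F2=~b2": 1.0, "F2=~b3": 1.0,
            "F2~F1": 0.5,
            "F1~~F1": 0.64, "F2~~F2": 0.64 * (1 - 0.25),
        }
        for ind in ("a1", "a2", "a3", "b1", "b2", "b3"):
            truth[f"{ind}~~{ind}"] = 0.36
        n_reps = 200
        covered = {k: 0 for k in truth}
        for r in range(n_reps):
            X = simulate_from_sem(gen, params, 5000, seed=1000 + r)
            fit = sem.fit_ml(fit_spec, X)
            assert fit.converged
            for k, v in truth.items():
                if abs(fit.estimates[k] - v) <= 3 * fit.standard_errors[k]:
                    covered[k] += 1
        for k, c in covered.items():
            assert c / n_reps >= 0.95, (k, c)

    def test_chi2_mean_matches_df(self):
        """Under a correct model, chi-square has mean ~ df."""
        gen, params = _two_factor_params()
        fit_spec = sem.parse_model(TWO_FACTOR)
        df_expected = None
        chis = []
        for r in range(200):
            X = simulate_from_sem(gen, params, 2000, seed=5000 + r)
            fit = sem.fit_ml(fit_spec, X)
            df_expected = fit.df
            chis.append(fit.chi2)
        assert abs(np.mean(chis) - df_expected) / df_expected < 0.15

    def test_listwise_deletion(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        df = pd.DataFrame({"y": y, "x": x})
        df.loc[:4, "x"] = np.nan
        fit = sem.fit_ml(sem.parse_model("y ~ x\n"), df)
        assert fit.n == 195

    def test_more_params_than_moments_rejected(self):
        text = "x1 ~~ x2\nx1 ~~ x3\nx2 ~~ x3\nF =~ x1 + x2 + x3\n"
        with pytest.raises(sem.SemError, match="more free parameters"):
            sem.fit_ml(sem.parse_model(text), sample_cov=np.eye(3), n=100)


class TestStandardize:
    def test_unit_variance_model_unchanged(self):
        gen, params = _two_factor_params()
        X = simulate_from_sem(gen, params, 20000, seed=11)
        fit = sem.fit_ml(sem.parse_model(TWO_FACTOR), X)
        # generated in the standardized metric: std path ~ generating beta
        assert fit.standardized["F2~F1"] == pytest.approx(0.5, abs=0.05)

    def test_direct_formula(self):
        """b = 2 with sd(x) = 1, sd(y) = 4 gives std beta 0.5 exactly."""
        spec = sem.parse_model("y ~ x\n", identification="none")
        ram_params = {"y~x": 2.0, "x~~x": 1.0, "y~~y": 12.0}  # var(y) = 4 + 12 = 16
        X = simulate_from_sem(spec, ram_params, 100000, seed=12)
        fit = sem.fit_ml(sem.parse_model("y ~ x\n"), X)
        sd_x = np.sqrt(fit.estimates["x~~x"])
        sd_y = np.sqrt(fit.estimates["y~x"] ** 2 * fit.estimates["x~~x"] + fit.estimates["y~~y"])
        assert fit.standardized["y~x"] == pytest.approx(
            fit.estimates["y~x"] * sd_x / sd_y, abs=1e-10
        )
        assert fit.standardized["y~x"] == pytest.approx(0.5, abs=0.02)

    def test_single_path_std_equals_correlation(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(3000)
        y = 0.6 * x + rng.standard_normal(3000)
        fit = sem.fit_ml(sem.parse_model("y ~ x\n"), pd.DataFrame({"y": y, "x": x}))
        assert fit.standardized["y~x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-6)

    def test_rescaling_invariance(self):
        """Multiplying an observed variable by a constant leaves the
        standardized solution unchanged under fix_first_loading."""
        gen, params = _two_factor_params()
        X = simulate_from_sem(gen, params, 3000, seed=14)
        spec = sem.parse_model(TWO_FACTOR)
        fit1 = sem.fit_ml(spec, X)
        X2 = X.copy()
        X2[:, 0] *= 37.0
        X2[:, 4] *= 0.01
        fit2 = sem.fit_ml(spec, X2)
        for k, v in fit1.standardized.items():
            assert fit2.standardized[k] == pytest.approx(v, abs=1e-5), k

    def test_relevance_flags(self):
        gen, params = _two_factor_params(beta=0.5)
        X = simulate_from_sem(gen, params, 5000, seed=15)
        fit = sem.fit_ml(sem.parse_model(TWO_FACTOR), X)
        assert fit.relevance_flags["F2~F1"] is True


class TestRmsea:
    def test_chi2_equal_df_is_zero(self):
        est, lo, hi = sem.rmsea(10.0, 10, 200)
        assert est == 0.0
        assert lo == 0.0

    def test_closed_form_value(self):
        est, _, _ = sem.rmsea(20.0, 10, 101)
        assert est == pytest.approx(0.1)

    def test_ci_solves_noncentral_tail(self):
        from scipy import stats as sps

        chi2, df, n = 42.0, 15, 150
        est, lo, hi = sem.rmsea(chi2, df, n)
        assert lo <= est <= hi
        lam_lo = lo**2 * df * (n - 1)
        lam_hi = hi**2 * df * (n - 1)
        assert sps.ncx2.cdf(chi2, df, lam_lo) == pytest.approx(0.95, abs=1e-6)
        assert sps.ncx2.cdf(chi2, df, lam_hi) == pytest.approx(0.05, abs=1e-6)

    def test_df_zero_rejected(self):
        with pytest.raises(sem.SemError, match="df"):
            sem.rmsea(5.0, 0, 100)

    def test_correct_model_rmsea_shrinks(self):
        """For a true model the RMSEA point estimate is near zero at large n."""
        gen, params = _two_factor_params()
        fit_spec = sem.parse_model(TWO_FACTOR)
        vals = []
        for r in range(50):
            X = simulate_from_sem(gen, params, 5000, seed=9000 + r)
            vals.append(sem.fit_ml(fit_spec, X).rmsea[0])
        assert np.median(vals) < 0.02


class TestModificationIndices:
    def test_free_parameters_never_reported(self):
        gen, params = _two_factor_params()
        X = simulate_from_sem(gen, params, 1000, seed=21)
        fit = sem.fit_ml(sem.parse_model(TWO_FACTOR), X)
        mi = sem.modification_indices(fit)
        assert "F2~F1" not in mi
        assert all(lab not in fit.estimates for lab in mi)

    def test_omitted_path_has_max_mi(self):
        """Dropping a real structural path (std beta 0.5) from the fitted
        model makes that path the top modification index."""
        gen, params = _two_factor_params(beta=0.5)
        X = simulate_from_sem(gen, params, 1000, seed=22)
        nolink = sem.parse_model("F1 =~ a1 + a2 + a3\nF2 =~ b1 + b2 + b3\n")
        fit = sem.fit_ml(nolink, X)
        mi = sem.modification_indices(fit)
        finite = {k: v for k, v in mi.items() if np.isfinite(v)}
        top = max(finite, key=finite.get)
        assert top in ("F2~F1", "F1~F2")

    def test_null_calibration(self):
        """A parameter that is truly zero in the generating model has MI below
        the chi-square(1) 95th percentile in >= 90% of replicates."""
        gen, params = _two_factor_params(beta=0.5)
        fit_spec = sem.parse_model(TWO_FACTOR)
        hits, total = 0, 0
        for r in range(200):
            X = simulate_from_sem(gen, params, 500, seed=30000 + r)
            fit = sem.fit_ml(fit_spec, X)
            mi = sem.modification_indices(fit, candidates=["a1~~b1"])
            if np.isfinite(mi.get("a1~~b1", np.nan)):
                total += 1
                hits += mi["a1~~b1"] < 3.84
        assert total > 150
        assert hits / total >= 0.90
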