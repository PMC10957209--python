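"""Unit tests of the SEM core: implied moments, the ML discrepancy, FIML,
fitting, standardization and robust standard errors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import mimicsem as ms
from mimicsem.model import MimicModelSpec, fit_model, fiml_loglik, implied_moments, ml_discrepancy


# --------------------------------------------------------------------------
# implied moments
# --------------------------------------------------------------------------


class TestImpliedMoments:
    def test_zero_loadings_give_identity(self):
        spec = MimicModelSpec(["a", "b", "c"], fixed={"lambda:a": 0.0})
        params = {f"lambda:{k}": 0.0 for k in "abc"}
        params |= {f"theta:{k}": 1.0 for k in "abc"} | {"psi": 1.0}
        Sigma, _ = implied_moments(spec, params)
        np.testing.assert_allclose(Sigma, np.eye(3))

    def test_two_indicator_hand_algebra(self):
        # loadings (1, 0.5), factor variance 1, residuals (1, 1)
        spec = MimicModelSpec(["a", "b"])
        Sigma, _ = implied_moments(
            spec, {"lambda:a": 1.0, "lambda:b": 0.5, "theta:a": 1.0, "theta:b": 1.0, "psi": 1.0}
        )
        np.testing.assert_allclose(Sigma, [[2.0, 0.5], [0.5, 1.25]])

    def test_null_path_kills_indicator_predictor_covariance(self):
        spec = MimicModelSpec(["a", "b"], ["x"])
        Sigma, _ = implied_moments(
            spec,
            {"lambda:a": 1.0, "lambda:b": 0.7, "theta:a": 0.5, "theta:b": 0.5,
             "psi": 1.0, "gamma:x": 0.0},
        )
        np.testing.assert_allclose(Sigma[:2, 2], 0.0)

    def test_incomplete_parameter_map_raises(self):
        spec = MimicModelSpec(["a", "b"], ["x"])
        with pytest.raises(ValueError, match="incomplete"):
            implied_moments(spec, {"lambda:b": 0.5})


# --------------------------------------------------------------------------
# ML discrepancy
# --------------------------------------------------------------------------


class TestMlDiscrepancy:
    def test_zero_at_equality(self):
        S = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        S = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert ml_discrepancy(S, np.eye(2)) == pytest.approx(4 - np.log(3) - 2, abs=1e-12)

    @given(st.permutations(range(4)))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 4 * np.eye(4)
        B = rng.standard_normal((4, 4))
        Sig = B @ B.T + 4 * np.eye(4)
        p = list(perm)
        F1 = ml_discrepancy(S, Sig)
        F2 = ml_discrepancy(S[np.ix_(p, p)], Sig[np.ix_(p, p)])
        assert F1 == pytest.approx(F2, rel=1e-10)

    def test_singular_sigma_reports_condition(self):
        S = np.eye(2)
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            ml_discrepancy(S, np.array([[1.0, 1.0], [1.0, 1.0]]))


# --------------------------------------------------------------------------
# FIML casewise likelihood
# --------------------------------------------------------------------------


class TestFimlLoglik:
    PARAMS = {
        "lambda:a": 1.0, "lambda:b": 0.5, "theta:a": 1.0, "theta:b": 1.0,
        "psi": 1.0, "nu:a": 0.3, "nu:b": -0.2,
    }

    def test_matches_complete_data_gaussian(self):
        spec = MimicModelSpec(["a", "b"])
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        ll = fiml_loglik(df, spec, self.PARAMS)
        Sigma, mu = implied_moments(spec, self.PARAMS)
        direct = float(sps.multivariate_normal(mu, Sigma).logpdf(df.to_numpy()).sum())
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_hand_specified_missing_pattern(self):
        # univariate/bivariate normal densities summed by hand (scipy oracle)
        spec = MimicModelSpec(["a", "b"])
        df = pd.DataFrame({"a": [0.5, np.nan, 1.2], "b": [0.1, 0.7, np.nan]})
        ll = fiml_loglik(df, spec, self.PARAMS)
        S = np.array([[2.0, 0.5], [0.5, 1.25]])
        m = np.array([0.3, -0.2])
        expected = (
            sps.multivariate_normal(m, S).logpdf([0.5, 0.1])
            + sps.norm(m[1], np.sqrt(S[1, 1])).logpdf(0.7)
            + sps.norm(m[0], np.sqrt(S[0, 0])).logpdf(1.2)
        )
        assert ll == pytest.approx(float(expected), abs=1e-10)

    def test_fully_missing_row_is_neutral(self):
        spec = MimicModelSpec(["a", "b"])
        df = pd.DataFrame({"a": [0.5, np.nan], "b": [0.1, np.nan]})
        with pytest.warns(UserWarning, match="1 row"):
            ll_with = fiml_loglik(df, spec, self.PARAMS)
        ll_without = fiml_loglik(df.iloc[:1], spec, self.PARAMS)
        assert ll_with == pytest.approx(ll_without, abs=1e-12)


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------


class TestFitModel:
    def test_saturated_two_indicator_model_fits_perfectly(self):
        # 2 indicators, 1 factor: parameters saturate the 3 moments
        rng = np.random.default_rng(2)
        eta = rng.standard_normal(2000)
        df = pd.DataFrame(
            {"a": eta + 0.8 * rng.standard_normal(2000), "b": 0.6 * eta + 0.9 * rng.standard_normal(2000)}
        )
        est = fit_model(df, MimicModelSpec(["a", "b"]), method="ml_complete")
        assert est.converged
        assert est.f_min == pytest.approx(0.0, abs=1e-7)

    def test_cfa_recovers_loadings_at_large_n(self):
        cfg = ms.SyntheticConfig(n_participants=100_000, seed=10, n_gray_regions=1,
                                 n_white_tracts=1, missing_rate=0.0)
        ds = ms.generate_dataset(cfg)
        est = fit_model(ds.cognition.scores, MimicModelSpec(ds.cognition.task_names), "ml_complete")
        got = [est.standardized[f"lambda:{t}"] for t in ds.cognition.task_names]
        np.testing.assert_allclose(got, cfg.loadings, atol=0.02)

    def test_degenerate_mimic_equals_ols_slope(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        y = 0.4 * x + rng.standard_normal(500)
        df = pd.DataFrame({"y": y, "x": x})
        spec = MimicModelSpec(["y"], ["x"], fixed={"theta:y": 0.0})
        est = fit_model(df, spec, method="ml_complete")
        ols = float(np.cov(x, y, ddof=0)[0, 1] / np.var(x))
        assert est.raw["gamma:x"] == pytest.approx(ols, abs=1e-6)

    def test_fiml_on_complete_data_equals_ml(self, small_frame, small_dataset):
        preds = ["SA_region01", "WMV_tract01", "CT_region05"]
        spec = MimicModelSpec(small_dataset.cognition.task_names, preds)
        e_ml = fit_model(small_frame, spec, "ml_complete")
        e_fi = fit_model(small_frame, spec, "fiml")
        for k in e_ml.raw:
            if not k.startswith("nu:"):
                assert e_fi.raw[k] == pytest.approx(e_ml.raw[k], abs=1e-6)

    def test_fiml_uses_partially_observed_rows(self, missing_dataset):
        data = ms.assemble_frame(missing_dataset.cognition, missing_dataset.brain)
        spec = MimicModelSpec(missing_dataset.cognition.task_names, ["SA_region01"])
        est = fit_model(data, spec, method="fiml")
        # more rows than listwise deletion would keep
        listwise = len(data.dropna())
        assert est.n_obs > listwise
        assert est.converged

    def test_equality_constraint_enforced_exactly_and_fits_worse(self, small_frame, small_dataset):
        preds = ["SA_region01", "SA_region02", "GMV_region03"]
        spec = MimicModelSpec(small_dataset.cognition.task_names, preds)
        free = fit_model(small_frame, spec, "ml_complete")
        equal = fit_model(small_frame, spec.with_equal_paths(), "ml_complete")
        g = [equal.raw[f"gamma:{p}"] for p in preds]
        assert g[0] == g[1] == g[2]
        assert equal.loglik <= free.loglik + 1e-8
        assert free.n_free - equal.n_free == len(preds) - 1

    def test_residual_variances_nonnegative(self, small_frame, small_dataset):
        spec = MimicModelSpec(small_dataset.cognition.task_names, ["MD_tract01"])
        est = fit_model(small_frame, spec, "ml_complete")
        assert all(est.raw[f"theta:{t}"] >= 0 for t in small_dataset.cognition.task_names)
        assert est.raw["psi"] >= 0


class TestStandardize:
    def test_scale_algebra(self):
        # loading 0.5, indicator implied SD 2, factor SD 1 -> standardized 0.25
        spec = MimicModelSpec(["a", "b"], fixed={"lambda:a": 1.0})
        est = ms.ParameterEstimates(
            raw={}, standardized={}, loglik=0.0, n_obs=100, converged=True, n_free=0,
            spec=spec, method="ml_complete",
            nu=np.zeros(2), lam=np.array([1.0, 0.5]), gamma=np.zeros(0),
            theta=np.array([3.0, 3.75]), psi=1.0,
            predictor_cov=np.zeros((0, 0)), predictor_means=np.zeros(0),
        )
        std = ms.standardize(est).standardized
        assert std["lambda:b"] == pytest.approx(0.5 * 1.0 / 2.0)

    def test_idempotent_on_standardized_solution(self, small_frame, small_dataset):
        spec = MimicModelSpec(small_dataset.cognition.task_names, ["SA_region01"])
        est = fit_model(small_frame, spec, "ml_complete")
        once = ms.standardize(est).standardized
        twice = ms.standardize(ms.standardize(est)).standardized
        assert once == twice

    def test_single_predictor_standardized_path_matches_latent_correlation(self, small_dataset, small_frame):
        spec = MimicModelSpec(small_dataset.cognition.task_names, ["SA_region01"])
        est = fit_model(small_frame, spec, "ml_complete")
        eta = small_dataset.truth["latent"]
        r = float(np.corrcoef(eta, small_frame["SA_region01"])[0, 1])
        assert est.standardized["gamma:SA_region01"] == pytest.approx(r, abs=0.03)


class TestSandwichSe:
    def test_positive_and_close_to_information_under_normality(self, small_frame, small_dataset):
        spec = MimicModelSpec(small_dataset.cognition.task_names, ["SA_region01"])
        est = fit_model(small_frame, spec, "ml_complete")
        se = ms.sandwich_se(small_frame, spec, est)
        assert all(v > 0 for v in se.values())
        info = est.vcov["se_information"]
        for k in se:
            assert se[k] == pytest.approx(info[k], rel=0.10)

    def test_heavy_tails_inflate_variance_parameter_ses(self):
        """Scaled-t(5) indicator residuals violate normality; the robust SEs
        must exceed the naive information SEs for the kurtosis-sensitive
        residual-variance parameters (Monte-Carlo confirms the robust SEs
        track the true sampling SD there while the naive ones undershoot)."""
        rng = np.random.default_rng(11)
        n = 20_000
        eta = rng.standard_normal(n)
        L = np.array([0.8, 0.7, 0.6, 0.5])
        resid_sd = np.sqrt(1 - L**2)
        t5 = rng.standard_t(5, size=(n, 4)) / np.sqrt(5 / 3)  # unit-variance t(5)
        Y = eta[:, None] * L + t5 * resid_sd
        df = pd.DataFrame(Y, columns=list("abcd"))
        spec = MimicModelSpec(list("abcd"))
        est = fit_model(df, spec, "ml_complete")
        se = ms.sandwich_se(df, spec, est)
        info = est.vcov["se_information"]
        ratios = [se[k] / info[k] for k in se if k.startswith("theta:")]
        assert all(r > 1.2 for r in ratios)
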