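"""Tests of chi-square, df, RMSEA, CFI/TLI, SRMR, AIC/BIC, latent R2 and
the likelihood-ratio test."""

import numpy as np
import pytest

import mimicsem as ms
from mimicsem.model import MimicModelSpec, fit_model
from mimicsem.indices import (
    chi_square,
    cfi_tli,
    information_criteria,
    latent_r2,
    likelihood_ratio_test,
    model_df,
    rmsea,
    srmr,
)


class TestChiSquareAndDf:
    def test_chi_square_scaling(self):
        assert chi_square(0.0, 500) == 0.0
        assert chi_square(0.01, 1000) == pytest.approx(10.0)
        assert chi_square(0.01, 2000) == pytest.approx(2 * chi_square(0.01, 1000))

    @pytest.mark.parametrize(
        "n_ind, expected", [(5, 5), (4, 2), (3, 0)]
    )
    def test_single_factor_cfa_df(self, n_ind, expected):
        # 5 indicators: 15 moments - 10 free parameters = 5
        spec = MimicModelSpec([f"t{i}" for i in range(n_ind)])
        assert model_df(spec) == expected

    def test_mimic_df_counts_saturated_predictor_block(self):
        spec = MimicModelSpec(["a", "b", "c", "d", "e"], ["x1", "x2"])
        # 7*8/2=28 moments; free: 4 lam + 5 theta + psi + 2 gamma + 3 phi = 15
        assert model_df(spec) == 13

    def test_fixed_zero_paths_raise_df(self):
        spec = MimicModelSpec(["a", "b", "c", "d", "e"], ["x1", "x2"])
        constrained = spec.with_paths_fixed_to_zero(["x1", "x2"])
        assert model_df(constrained) == model_df(spec) + 2


class TestRmsea:
    def test_back_calculation_of_reported_value(self):
        # chi2=156.404, df=5, N=10,095 -> 0.055 at 3 decimals
        point, _ = rmsea(156.404, 5, 10_095)
        assert round(point, 3) == 0.055

    def test_truncation_below_df(self):
        point, (lo, hi) = rmsea(3.0, 5, 1000)
        assert point == 0.0
        assert lo <= point <= hi

    def test_ci_brackets_point(self):
        point, (lo, hi) = rmsea(80.0, 20, 500)
        assert lo <= point <= hi

    def test_df_zero_is_undefined(self):
        with pytest.raises(ValueError):
            rmsea(1.0, 0, 100)


class TestCfiTli:
    def test_perfect_fit(self):
        cfi, tli = cfi_tli(5.0, 5, 1000.0, 10)
        assert cfi == 1.0

    def test_hand_arithmetic(self):
        cfi, _ = cfi_tli(150.0, 5, 1000.0, 10)
        assert cfi == pytest.approx(1 - 145 / 990, abs=1e-12)

    def test_tli_exceeds_one_cfi_does_not(self):
        cfi, tli = cfi_tli(2.0, 5, 1000.0, 10)
        assert tli > 1.0
        assert cfi == 1.0

    def test_baseline_worse_than_target_required(self):
        with pytest.warns(UserWarning):
            cfi, _ = cfi_tli(500.0, 5, 100.0, 10)
        assert 0.0 <= cfi <= 1.0


class TestSrmr:
    def test_zero_at_equality(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert srmr(S, S) == 0.0

    def test_hand_arithmetic(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        M = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert srmr(S, M) == pytest.approx(np.sqrt(0.01 / 3), abs=1e-12)

    def test_invariant_to_common_rescaling(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        M = np.array([[1.0, 0.4], [0.4, 1.0]])
        D = np.diag([3.0, 0.5])
        assert srmr(D @ S @ D, D @ M @ D) == pytest.approx(srmr(S, M), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            srmr(np.diag([1.0, 0.0]), np.eye(2))


class TestInformationCriteria:
    def test_arithmetic(self):
        assert information_criteria(0.0, 0, 10) == (0.0, 0.0)
        aic, bic = information_criteria(-100.0, 3, 100)
        assert aic == pytest.approx(206.0)
        assert bic == pytest.approx(200 + 3 * np.log(100))
        assert bic > aic  # n > e^2 and k > 0


class TestLatentR2:
    def test_pure_cfa_undefined(self, small_frame, small_dataset, cfa_spec):
        est = fit_model(small_frame, cfa_spec, "ml_complete")
        with pytest.raises(ValueError, match="undefined"):
            latent_r2(est)

    def test_single_standardized_path_squares(self, small_frame, small_dataset):
        spec = MimicModelSpec(small_dataset.cognition.task_names, ["SA_region01"])
        est = fit_model(small_frame, spec, "ml_complete")
        g = est.standardized["gamma:SA_region01"]
        r2, r2_adj = latent_r2(est)
        assert r2 == pytest.approx(g**2, abs=1e-10)
        assert r2_adj <= r2

    def test_recovery_against_population_oracle(self):
        cfg = ms.partial_overlap_config(n_participants=10_000, seed=13, missing_rate=0.0)
        ds = ms.generate_dataset(cfg)
        frame = ms.assemble_frame(ds.cognition, ds.brain)
        preds = sorted(cfg.true_paths)
        pop = ms.population_r2(cfg, preds)
        spec = MimicModelSpec(ds.cognition.task_names, preds)
        est = fit_model(frame, spec, "ml_complete")
        r2, _ = latent_r2(est)
        assert r2 == pytest.approx(pop, abs=0.02)


class TestLikelihoodRatioTest:
    def test_identical_models_give_null_result(self, small_frame, small_dataset):
        spec = MimicModelSpec(small_dataset.cognition.task_names, ["SA_region01"])
        est = fit_model(small_frame, spec, "ml_complete")
        d, ddf, p = likelihood_ratio_test(est, est)
        assert (d, ddf, p) == (0.0, 0, 1.0)

    def test_invariant_to_predictor_order(self, small_frame, small_dataset):
        tasks = small_dataset.cognition.task_names
        preds = ["SA_region01", "WMV_tract01", "CT_region02"]
        free_a = fit_model(small_frame, MimicModelSpec(tasks, preds), "ml_complete")
        free_b = fit_model(small_frame, MimicModelSpec(tasks, preds[::-1]), "ml_complete")
        con_a = fit_model(
            small_frame, MimicModelSpec(tasks, preds).with_paths_fixed_to_zero(["CT_region02"]),
            "ml_complete",
        )
        con_b = fit_model(
            small_frame, MimicModelSpec(tasks, preds[::-1]).with_paths_fixed_to_zero(["CT_region02"]),
            "ml_complete",
        )
        d_a, _, _ = likelihood_ratio_test(free_a, con_a)
        d_b, _, _ = likelihood_ratio_test(free_b, con_b)
        assert d_a == pytest.approx(d_b, abs=1e-5)

    def test_non_nested_specs_raise(self, small_frame, small_dataset):
        tasks = small_dataset.cognition.task_names
        a = fit_model(small_frame, MimicModelSpec(tasks, ["SA_region01"]), "ml_complete")
        b = fit_model(small_frame, MimicModelSpec(tasks, ["WMV_tract01"]), "ml_complete")
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)


class TestFitIndexSet:
    def test_near_saturated_model_scores_cleanly(self, small_frame, small_dataset):
        spec = MimicModelSpec(small_dataset.cognition.task_names)
        est = fit_model(small_frame[spec.indicators], spec, "ml_complete")
        fx = ms.fit_index_set(small_frame[spec.indicators], spec, est)
        # data generated from the fitted structure: excellent fit expected
        assert fx.df == 5
        assert fx.rmsea < 0.03
        assert fx.cfi > 0.99
        assert fx.srmr < 0.02
        assert fx.chi2 >= 0.0

    def test_nested_r2_monotone(self, small_frame, small_dataset):
        tasks = small_dataset.cognition.task_names
        preds = ["SA_region01", "SA_region02", "GMV_region03"]
        free = fit_model(small_frame, MimicModelSpec(tasks, preds), "ml_complete")
        sub = fit_model(
            small_frame,
            MimicModelSpec(tasks, preds).with_paths_fixed_to_zero(["GMV_region03"]),
            "ml_complete",
        )
        assert latent_r2(free)[0] >= latent_r2(sub)[0] - 1e-10
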