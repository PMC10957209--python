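"""Tests of the synthetic-data generator and its closed-form R2 oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mimicsem as ms
from mimicsem.simulate import (
    SyntheticConfig,
    generate_dataset,
    independent_config,
    partial_overlap_config,
    population_r2,
    redundant_config,
)


def _small(**kw):
    base = dict(n_participants=500, seed=1, n_gray_regions=3, n_white_tracts=2)
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenerate:
    def test_default_feature_count_is_162(self):
        assert SyntheticConfig().n_features == 34 * 3 + 20 * 3 == 162

    def test_zero_missing_rate_gives_complete_cognition(self):
        ds = generate_dataset(_small(missing_rate=0.0))
        assert not ds.cognition.scores.isna().to_numpy().any()

    def test_missing_rate_within_binomial_error(self):
        ds = generate_dataset(_small(n_participants=20_000, missing_rate=0.1))
        rate = ds.cognition.missing_rate
        # 3 SD binomial band around 0.1 for 100k cells
        assert abs(rate - 0.1) < 3 * np.sqrt(0.1 * 0.9 / (20_000 * 5))
        assert not ds.brain.features.isna().to_numpy().any()

    def test_same_seed_bit_identical_different_seed_not(self):
        a = generate_dataset(_small(seed=5, missing_rate=0.05))
        b = generate_dataset(_small(seed=5, missing_rate=0.05))
        c = generate_dataset(_small(seed=6, missing_rate=0.05))
        assert a.cognition.scores.equals(b.cognition.scores)
        assert a.brain.features.equals(b.brain.features)
        assert not a.brain.features.equals(c.brain.features)

    def test_null_paths_leave_predictors_uncorrelated_with_indicators(self):
        ds = generate_dataset(_small(n_participants=50_000, missing_rate=0.0))
        X = ds.brain.features.to_numpy()
        Y = ds.cognition.scores.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        Ys = (Y - Y.mean(0)) / Y.std(0)
        corr = Xs.T @ Ys / len(X)
        assert np.max(np.abs(corr)) < 0.02

    def test_sample_covariance_matches_population(self):
        cfg = _small(n_participants=100_000, missing_rate=0.0,
                     true_paths={"SA_region01": 0.2})
        ds = generate_dataset(cfg)
        X = ds.brain.features.to_numpy()
        S = np.cov(X, rowvar=False, ddof=0)
        np.testing.assert_allclose(S, cfg.feature_covariance(), atol=0.012)

    def test_gmv_composed_from_ct_and_sa(self):
        cfg = _small(n_participants=50_000, missing_rate=0.0, gmv_composition_noise=0.2)
        ds = generate_dataset(cfg)
        f = ds.brain.features
        comp = f["CT_region01"] + f["SA_region01"]
        r = np.corrcoef(comp, f["GMV_region01"])[0, 1]
        # implied correlation sqrt(1 - tau^2) of the standardized composite
        assert r == pytest.approx(np.sqrt(1 - 0.2**2), abs=0.01)

    def test_latent_variance_near_unity_and_paths_standardized(self):
        cfg = _small(n_participants=100_000, missing_rate=0.0,
                     true_paths={"SA_region01": 0.25, "WMV_tract01": 0.2})
        ds = generate_dataset(cfg)
        eta = ds.truth["latent"]
        assert np.var(eta) == pytest.approx(1.0, abs=0.02)
        r = np.corrcoef(eta, ds.brain.features["SA_region01"])[0, 1]
        pop = float(cfg.feature_covariance()[cfg.feature_names().index("SA_region01")]
                    @ cfg.path_vector())
        assert r == pytest.approx(pop, abs=0.02)

    def test_invalid_parameterizations_name_the_block(self):
        with pytest.raises(ValueError, match="cross-tissue"):
            _small(cross_tissue_rho=0.5, within_metric_rho=0.3).validate()
        with pytest.raises(ValueError, match="GMV composition"):
            _small(gmv_composition_noise=0.0).validate()
        with pytest.raises(ValueError, match="positive definite"):
            _small(within_metric_rho=0.7, cross_metric_rho=0.7, cross_tissue_rho=0.3).validate()
        with pytest.raises(ValueError, match="latent variance"):
            _small(true_paths={"SA_region01": 0.9, "SA_region02": 0.9}).validate()


class TestPopulationR2:
    def test_empty_subset_is_zero(self):
        assert population_r2(_small(), []) == 0.0

    def test_isolated_single_predictor_equals_gamma_squared(self):
        # no correlated co-predictors: all correlations off
        cfg = _small(within_metric_rho=0.0, cross_metric_rho=0.0, cross_tissue_rho=0.0,
                     gray_metrics=("CT", "SA"), true_paths={"SA_region01": 0.3})
        assert population_r2(cfg, ["SA_region01"]) == pytest.approx(0.09, abs=1e-12)

    def test_unknown_predictor_raises(self):
        with pytest.raises(KeyError):
            population_r2(_small(), ["CT_nowhere"])

    def test_joint_between_max_and_sum_under_cross_tissue_overlap(self):
        cfg = _small(cross_tissue_rho=0.25, within_metric_rho=0.3, cross_metric_rho=0.35,
                     true_paths={"SA_region01": 0.2, "WMV_tract01": 0.2})
        gray = [n for n in cfg.feature_names() if n.split("_")[0] in cfg.gray_metrics]
        white = [n for n in cfg.feature_names() if n.split("_")[0] in cfg.white_metrics]
        rg = population_r2(cfg, gray)
        rw = population_r2(cfg, white)
        rj = population_r2(cfg, gray + white)
        assert max(rg, rw) < rj < rg + rw

    @given(st.lists(st.integers(min_value=0, max_value=14), min_size=0, max_size=8, unique=True),
           st.integers(min_value=0, max_value=14))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_under_superset(self, idx, extra):
        cfg = _small(true_paths={"SA_region01": 0.2, "WMV_tract01": 0.15, "CT_region02": -0.1})
        names = cfg.feature_names()
        subset = [names[i] for i in idx]
        bigger = subset + ([names[extra]] if names[extra] not in subset else [])
        assert population_r2(cfg, bigger) >= population_r2(cfg, subset) - 1e-10


class TestStudyConfigs:
    def test_partial_overlap_calibration_hits_targets(self):
        cfg = partial_overlap_config(n_participants=100)
        gray = [n for n in cfg.feature_names() if n.split("_")[0] in cfg.gray_metrics]
        white = [n for n in cfg.feature_names() if n.split("_")[0] in cfg.white_metrics]
        assert population_r2(cfg, gray) == pytest.approx(0.154, abs=0.002)
        assert population_r2(cfg, white) == pytest.approx(0.124, abs=0.002)
        assert population_r2(cfg, gray + white) == pytest.approx(0.190, abs=0.002)

    def test_scenario_configs_realize_their_partition(self):
        for factory, check in (
            (redundant_config, lambda g, w, j: j <= max(g, w) + 0.005),
            (independent_config, lambda g, w, j: abs(j - (g + w)) < 0.005),
        ):
            cfg = factory(n_participants=100)
            gray = [n for n in cfg.feature_names() if n.split("_")[0] in cfg.gray_metrics]
            white = [n for n in cfg.feature_names() if n.split("_")[0] in cfg.white_metrics]
            g, w, j = (population_r2(cfg, s) for s in (gray, white, gray + white))
            assert check(g, w, j)

    def test_tiv_composite_carries_configured_signal(self):
        cfg = partial_overlap_config(n_participants=100, include_tiv=True)
        assert population_r2(cfg, ["TIV"]) == pytest.approx(0.068, abs=0.002)


def test_csv_round_trip(tmp_path):
    ds = ms.generate_dataset(_small(missing_rate=0.1, include_tiv=True, include_sex=True))
    manifest = ds.to_csv(tmp_path)
    cog, brain = ms.read_dataset(manifest["cognition"], manifest["brain"])
    np.testing.assert_array_equal(
        cog.scores.to_numpy(), ds.cognition.scores.to_numpy()
    )
    np.testing.assert_allclose(
        brain.features.to_numpy(), ds.brain.features.to_numpy(), rtol=0, atol=1e-12
    )
    assert "TIV" in brain.covariates.columns
    assert "sex" in brain.covariates.columns
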