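"""End-to-end study orchestration.

The analysis splits the sample into a model-building fraction (default
15%) and a validation remainder; regularized models run on the building
sample only, and the surviving predictors define the unpenalized models
fitted to the validation sample (a leakage guard: survivor sets are a pure
function of the building data).  Variance partitioning then compares the
adjusted R-squared of the gray-only, white-only and combined survivor
models and classifies the result as redundant, independent or partially
overlapping information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import FitIndexSet, fit_index_set, information_criteria, latent_r2, likelihood_ratio_test
from .lasso import fit_path
from .model import MimicModelSpec, ParameterEstimates, fit_model, sandwich_se
from .stability import run_stability
from .tables import (
    BrainFeatureTable,
    CognitionTable,
    assemble_frame,
    parse_feature_name,
    standardize_columns,
    tissue_of_metric,
)

log = logging.getLogger("mimicsem")


@dataclass
class StudyConfig:
    """Knobs of the full pipeline."""

    build_fraction: float = 0.15
    seed: int = 0
    include_tiv: bool = False
    stratify_by_sex: bool = False
    overlap_tolerance: float = 0.01  # delta for scenario classification
    n_lambda: int = 30
    stability_B: int = 0  # 0 disables the stability stage
    stability_fraction: float = 0.15
    stability_contexts: tuple = ("gray", "white", "combined")
    method: str = "fiml"
    expected_gray_regions: int | None = 34
    expected_white_tracts: int | None = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.build_fraction < 1.0:
            raise ValueError("build_fraction must lie in (0, 1)")


@dataclass
class StudyReport:
    """Everything the pipeline computes, Table-1 style."""

    measurement_fit: FitIndexSet
    per_roi_estimates: pd.DataFrame
    model_fits: dict  # model name -> FitIndexSet (or None when degenerate)
    survivors: dict  # model name -> list of predictor names
    estimates: dict  # model name -> ParameterEstimates
    lrt_results: pd.DataFrame
    overlap_class: str
    r2_table: pd.DataFrame
    equality_tests: pd.DataFrame | None = None
    stability: dict | None = None  # model name -> StabilityReport
    variants: dict | None = None
    seed: int = 0


# --------------------------------------------------------------------------
# sample handling
# --------------------------------------------------------------------------


def split_sample(n_rows: int, build_fraction: float = 0.15, seed: int = 0):
    """Disjoint, exhaustive (build, validate) row-index sets.

    The building set holds floor(fraction * n) rows; with n = 11,876 and a
    15% fraction this gives 1,781 building and 10,095 validation rows.
    """
    if not 0.0 < build_fraction < 1.0:
        raise ValueError("build_fraction must lie in (0, 1)")
    m = int(np.floor(build_fraction * n_rows))
    if m < 1 or n_rows - m < 1:
        raise ValueError(f"n={n_rows} is too small to split at fraction {build_fraction}")
    perm = np.random.default_rng(seed).permutation(n_rows)
    return np.sort(perm[:m]), np.sort(perm[m:])


def validate_feature_counts(brain: BrainFeatureTable, config: StudyConfig) -> None:
    """Check the expected atlas structure (regions per metric) when the
    configuration states it; bilateral averaging is assumed done upstream."""
    schema = brain.schema()
    for tissue, expected in (
        ("gray", config.expected_gray_regions),
        ("white", config.expected_white_tracts),
    ):
        if expected is None:
            continue
        for metric, grp in schema[schema.tissue == tissue].groupby("metric"):
            if len(grp) != expected:
                raise ValueError(
                    f"metric {metric} has {len(grp)} regions; expected {expected} "
                    f"for {tissue} matter (set expected_*=None to disable this check)"
                )


# --------------------------------------------------------------------------
# per-ROI single-predictor models
# --------------------------------------------------------------------------


def run_per_roi_models(
    data: pd.DataFrame,
    indicators: list[str],
    feature_names: list[str],
    method: str = "fiml",
    robust: bool = True,
) -> pd.DataFrame:
    """One single-predictor MIMIC per (region, metric).

    Returns a tidy table of standardized path estimates with sandwich
    standard errors (of the raw path); per-model failures are recorded in
    the table rather than raised.
    """
    rows = []
    for name in feature_names:
        try:
            metric, region = parse_feature_name(name)
        except ValueError:
            metric, region = "none", name
        spec = MimicModelSpec(indicators, [name])
        try:
            est = fit_model(data, spec, method=method, compute_saturated=False)
            se = np.nan
            if robust:
                se = sandwich_se(data, spec, est).get(f"gamma:{name}", np.nan)
            rows.append(
                {
                    "predictor": name,
                    "tissue": tissue_of_metric(metric),
                    "metric": metric,
                    "region": region,
                    "beta_raw": est.raw[f"gamma:{name}"],
                    "beta_std": est.standardized[f"gamma:{name}"],
                    "se_raw": se,
                    "converged": est.converged,
                    "error": "",
                }
            )
        except Exception as exc:
            log.warning("per-ROI model for %s failed: %s", name, exc)
            rows.append(
                {
                    "predictor": name,
                    "tissue": tissue_of_metric(metric),
                    "metric": metric,
                    "region": region,
                    "beta_raw": np.nan,
                    "beta_std": np.nan,
                    "se_raw": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# scenario classification
# --------------------------------------------------------------------------


def classify_overlap(r2_gray: float, r2_white: float, r2_joint: float, tolerance: float = 0.01) -> str:
    """Label the variance partition as ``redundant`` (joint ~ max of the
    parts), ``independent`` (joint ~ sum of the parts) or
    ``partially_overlapping`` (strictly between)."""
    for v in (r2_gray, r2_white, r2_joint):
        if not 0.0 <= v <= 1.0:
            raise ValueError("R-squared inputs must lie in [0, 1]")
    hi = max(r2_gray, r2_white)
    if r2_joint < hi - tolerance:
        raise ValueError(
            f"inconsistent inputs: joint R2 {r2_joint:.4f} is below the best single-"
            f"tissue R2 {hi:.4f} by more than {tolerance}"
        )
    redundant = r2_joint <= hi + tolerance
    independent = r2_joint >= r2_gray + r2_white - tolerance
    if redundant and independent:
        # degenerate region (one part explains ~nothing); pick the closer bound
        return "redundant" if (r2_joint - hi) <= (r2_gray + r2_white - r2_joint) else "independent"
    if redundant:
        return "redundant"
    if independent:
        return "independent"
    return "partially_overlapping"


# --------------------------------------------------------------------------
# tissue comparison core
# --------------------------------------------------------------------------


def _metric_columns(feature_names: list[str]) -> dict:
    by_metric: dict[str, list[str]] = {}
    for name in feature_names:
        metric, _ = parse_feature_name(name)
        by_metric.setdefault(metric, []).append(name)
    return by_metric


def run_tissue_comparison(
    build_data: pd.DataFrame,
    validate_data: pd.DataFrame,
    indicators: list[str],
    feature_names: list[str],
    config: StudyConfig | None = None,
    extra_predictors: list[str] | None = None,
) -> StudyReport:
    """Regularize on the building sample, validate on the held-out sample.

    Stages: (1) BIC-selected lasso paths for each per-metric model, each
    per-tissue model and the combined model on the building data; (2)
    unpenalized refits of the survivor-defined models on the validation
    data; (3) likelihood-ratio tests of the combined model against
    versions with all gray (or all white) paths constrained to zero; (4)
    fit indices and (adjusted) R-squared per model, plus the overlap
    classification.
    """
    config = config or StudyConfig()
    if len(build_data) == 0 or len(validate_data) == 0:
        raise ValueError("both samples must be nonempty")
    by_metric = _metric_columns(feature_names)
    gray_cols = [n for n in feature_names if tissue_of_metric(parse_feature_name(n)[0]) == "gray"]
    white_cols = [n for n in feature_names if tissue_of_metric(parse_feature_name(n)[0]) == "white"]
    extra = list(extra_predictors or [])

    model_columns = {f"metric:{m}": cols for m, cols in by_metric.items()}
    model_columns["gray"] = gray_cols
    model_columns["white"] = white_cols
    model_columns["combined"] = gray_cols + white_cols

    # -- stage 1: regularized selection on the building sample -------------
    survivors: dict[str, list[str]] = {}
    for name, cols in model_columns.items():
        spec = MimicModelSpec(indicators, cols)
        frame = standardize_columns(build_data[indicators + cols], indicators + cols)
        path = fit_path(frame, spec, n_lambda=config.n_lambda)
        survivors[name] = path.surviving
        log.info("regularization %-12s: %d of %d predictors survive", name, len(path.surviving), len(cols))

    # -- stage 2: survivor-defined validation fits -------------------------
    fits: dict[str, FitIndexSet | None] = {}
    estimates: dict[str, ParameterEstimates] = {}
    r2_rows = []
    for name in ("gray", "white", "combined"):
        surv = survivors[name] + extra
        if not surv:
            warnings.warn(f"model {name!r} has an empty survivor set; R2 reported as 0")
            fits[name] = None
            r2_rows.append({"model": name, "n_predictors": 0, "r2": 0.0, "r2_adj": 0.0,
                            "aic": np.nan, "bic": np.nan})
            continue
        spec = MimicModelSpec(indicators, surv)
        frame = standardize_columns(
            validate_data[indicators + surv], indicators + surv
        )
        est = fit_model(frame, spec, method=config.method)
        estimates[name] = est
        fx = fit_index_set(frame, spec, est)
        fits[name] = fx
        r2_rows.append(
            {
                "model": name,
                "n_predictors": len(surv),
                "r2": fx.r2,
                "r2_adj": fx.r2_adj,
                "aic": fx.aic,
                "bic": fx.bic,
            }
        )
    r2_table = pd.DataFrame(r2_rows).set_index("model")

    # -- stage 3: nested tissue tests on the combined model ----------------
    lrt_rows = []
    if "combined" in estimates:
        comb_spec = estimates["combined"].spec
        comb_surv = list(comb_spec.predictors)
        frame = standardize_columns(validate_data[indicators + comb_surv], indicators + comb_surv)
        for tissue, cols in (("gray", gray_cols), ("white", white_cols)):
            zeroed = [c for c in comb_surv if c in set(cols)]
            if not zeroed:
                continue
            constrained = fit_model(
                frame, comb_spec.with_paths_fixed_to_zero(zeroed), method=config.method
            )
            d_chi2, d_df, p = likelihood_ratio_test(estimates["combined"], constrained)
            aic_c, bic_c = information_criteria(constrained.loglik, constrained.n_free, constrained.n_obs)
            fx = fits["combined"]
            lrt_rows.append(
                {
                    "constrained_tissue": tissue,
                    "delta_chi2": d_chi2,
                    "delta_df": d_df,
                    "p_value": p,
                    "aic_diff": aic_c - fx.aic,
                    "bic_diff": bic_c - fx.bic,
                }
            )
    lrt_results = pd.DataFrame(lrt_rows)

    def _adj(name):
        return float(r2_table.loc[name, "r2_adj"])

    overlap = classify_overlap(_adj("gray"), _adj("white"), _adj("combined"), config.overlap_tolerance)

    return StudyReport(
        measurement_fit=None,
        per_roi_estimates=pd.DataFrame(),
        model_fits=fits,
        survivors=survivors,
        estimates=estimates,
        lrt_results=lrt_results,
        overlap_class=overlap,
        r2_table=r2_table,
        seed=config.seed,
    )


# --------------------------------------------------------------------------
# equality-constraint tests
# --------------------------------------------------------------------------


def equality_constraint_test(data: pd.DataFrame, spec: MimicModelSpec, method: str = "fiml") -> dict:
    """Free versus all-paths-equal comparison for one multi-predictor model.

    Returns the LRT (delta df = k - 1) together with AIC/BIC differences;
    negative AIC/BIC differences favor the free model.
    """
    k = sum(1 for p in spec.predictors if f"gamma:{p}" not in spec.fixed)
    if k < 2:
        raise ValueError("equality test needs at least two free predictor paths")
    free = fit_model(data, spec, method=method)
    equal = fit_model(data, spec.with_equal_paths(), method=method)
    d_chi2, d_df, p = likelihood_ratio_test(free, equal)
    aic_f, bic_f = information_criteria(free.loglik, free.n_free, free.n_obs)
    aic_e, bic_e = information_criteria(equal.loglik, equal.n_free, equal.n_obs)
    return {
        "delta_chi2": d_chi2,
        "delta_df": d_df,
        "p_value": p,
        "aic_free": aic_f,
        "aic_equal": aic_e,
        "bic_free": bic_f,
        "bic_equal": bic_e,
        "aic_diff": aic_f - aic_e,
        "bic_diff": bic_f - bic_e,
        "free_preferred_aic": aic_f < aic_e,
        "free_preferred_bic": bic_f < bic_e,
    }


# --------------------------------------------------------------------------
# TIV and sex-stratified variants
# --------------------------------------------------------------------------


def run_variants(
    build_data: pd.DataFrame,
    validate_data: pd.DataFrame,
    indicators: list[str],
    feature_names: list[str],
    config: StudyConfig,
    survivors_combined: list[str] | None = None,
    tiv_column: str = "TIV",
    sex_column: str = "sex",
) -> dict:
    """Supplementary analyses: the TIV-only model, the TIV-augmented
    combined model, and per-sex reruns of the tissue comparison."""
    out: dict = {}
    full = pd.concat([build_data, validate_data], axis=0, ignore_index=True)

    if config.include_tiv:
        if tiv_column not in validate_data.columns:
            raise ValueError(f"TIV requested but column {tiv_column!r} is absent")
        spec_tiv = MimicModelSpec(indicators, [tiv_column])
        frame = standardize_columns(validate_data[indicators + [tiv_column]], None)
        est_tiv = fit_model(frame, spec_tiv, method=config.method)
        out["tiv_only"] = {
            "estimates": est_tiv,
            "r2": latent_r2(est_tiv)[0],
            "r2_adj": latent_r2(est_tiv)[1],
        }
        if survivors_combined is None:
            spec_c = MimicModelSpec(indicators, feature_names)
            bframe = standardize_columns(build_data[indicators + feature_names], None)
            survivors_combined = fit_path(bframe, spec_c, n_lambda=config.n_lambda).surviving
        aug = survivors_combined + [tiv_column]
        spec_aug = MimicModelSpec(indicators, aug)
        frame = standardize_columns(validate_data[indicators + aug], None)
        est_aug = fit_model(frame, spec_aug, method=config.method)
        fx = fit_index_set(frame, spec_aug, est_aug)
        out["combined_plus_tiv"] = {"estimates": est_aug, "fit": fx,
                                    "r2": fx.r2, "r2_adj": fx.r2_adj}

    if config.stratify_by_sex:
        if sex_column not in full.columns:
            raise ValueError(f"sex stratification requested but column {sex_column!r} is absent")
        by_sex = {}
        for level, grp in full.groupby(sex_column):
            grp = grp.reset_index(drop=True)
            b_idx, v_idx = split_sample(len(grp), config.build_fraction, config.seed)
            by_sex[str(level)] = run_tissue_comparison(
                grp.iloc[b_idx], grp.iloc[v_idx], indicators, feature_names, config
            )
        out["by_sex"] = by_sex
    return out


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------


def run_study(
    cognition: CognitionTable,
    brain: BrainFeatureTable,
    config: StudyConfig | None = None,
    per_roi: bool = True,
    equality_tests: bool = False,
) -> StudyReport:
    """Run the complete analysis on one dataset.

    Orchestrates the sample split, the measurement model on the validation
    sample, per-ROI models, the regularized tissue comparison, optional
    equality-constraint tests and stability selection, and the TIV/sex
    variants when configured.
    """
    config = config or StudyConfig()
    validate_feature_counts(brain, config)
    data = assemble_frame(cognition, brain)
    indicators = cognition.task_names
    feature_names = brain.feature_names

    b_idx, v_idx = split_sample(len(data), config.build_fraction, config.seed)
    build_df = data.iloc[b_idx].reset_index(drop=True)
    valid_df = data.iloc[v_idx].reset_index(drop=True)
    log.info("split: %d building, %d validation rows", len(b_idx), len(v_idx))

    cfa = MimicModelSpec(indicators)
    cfa_est = fit_model(valid_df, cfa, method=config.method)
    measurement_fit = fit_index_set(valid_df, cfa, cfa_est)

    report = run_tissue_comparison(build_df, valid_df, indicators, feature_names, config)
    report.measurement_fit = measurement_fit
    report.seed = config.seed

    if per_roi:
        frame = standardize_columns(valid_df, feature_names)
        report.per_roi_estimates = run_per_roi_models(frame, indicators, feature_names, config.method)

    if equality_tests:
        rows = []
        for metric, cols in _metric_columns(feature_names).items():
            surv = [c for c in report.survivors.get(f"metric:{metric}", []) ]
            if len(surv) < 2:
                continue
            frame = standardize_columns(valid_df[indicators + surv], None)
            res = equality_constraint_test(frame, MimicModelSpec(indicators, surv), config.method)
            res["model"] = f"metric:{metric}"
            rows.append(res)
        report.equality_tests = pd.DataFrame(rows) if rows else None

    if config.stability_B > 0:
        report.stability = {}
        for name in config.stability_contexts:
            cols = [c for c in feature_names if name == "combined"
                    or tissue_of_metric(parse_feature_name(c)[0]) == name]
            rep = run_stability(
                data,
                MimicModelSpec(indicators, cols),
                B=config.stability_B,
                fraction=config.stability_fraction,
                base_seed=config.seed,
                n_lambda=config.n_lambda,
            )
            report.stability[name] = rep

    if config.include_tiv or config.stratify_by_sex:
        full_build = assemble_frame(cognition, brain).iloc[b_idx].reset_index(drop=True)
        full_valid = assemble_frame(cognition, brain).iloc[v_idx].reset_index(drop=True)
        report.variants = run_variants(
            full_build,
            full_valid,
            indicators,
            feature_names,
            config,
            survivors_combined=report.survivors.get("combined"),
        )
    return report
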