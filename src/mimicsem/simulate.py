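"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a multimodal developmental-imaging study: five
cognitive task scores measuring one latent factor (standardized loadings
spanning roughly 0.41-0.74), and region-by-metric brain features — three
gray-matter metrics (CT, SA, GMV) over cortical regions and three
white-matter metrics (FA, MD, WMV) over bilateral tracts — with a sparse
set of true standardized effects on the latent factor.

The feature covariance is a nested factor structure chosen as the minimal
parameterization reproducing partial overlap of predictive information:

* a global factor with loading sqrt(cross_tissue_rho) on every feature,
  so any cross-tissue pair correlates at ``cross_tissue_rho``;
* one factor per metric raising same-metric correlations to
  ``within_metric_rho``;
* one factor per (tissue, region) raising same-region cross-metric
  correlations to ``cross_metric_rho``.

Gray-matter volume is not drawn independently: each GMV column is a
rescaled sum of the region's CT and SA plus Gaussian noise with residual
SD ``gmv_composition_noise``, mimicking the near-deterministic composition
of volume from thickness and area.  Positive definiteness holds by
construction whenever the parameter constraints below are met.

Latent scores are realized explicitly and archived in the dataset's truth
record, so downstream estimators can be checked against ground truth that
a real study cannot provide.  Missing entries are deleted completely at
random, in the cognition columns only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .tables import BrainFeatureTable, CognitionTable, GRAY_METRICS, WHITE_METRICS

DEFAULT_LOADINGS = (0.74, 0.70, 0.53, 0.50, 0.41)
DEFAULT_TASKS = ("reading", "vocabulary", "rey_verbal", "little_man", "flanker")


@dataclass
class SyntheticConfig:
    """Parameterization of one synthetic study population.

    ``true_paths`` maps feature names (``<metric>_<region>``) to population
    standardized effects on the latent factor; features not listed have no
    direct effect.  ``gmv_composition_noise`` is the residual SD left in a
    GMV column after its CT+SA composite (0 < noise <= 1; small values make
    GMV nearly deterministic).
    """

    n_participants: int = 1000
    loadings: Sequence[float] = DEFAULT_LOADINGS
    task_names: Sequence[str] = DEFAULT_TASKS
    n_gray_regions: int = 34
    n_white_tracts: int = 20
    gray_metrics: Sequence[str] = GRAY_METRICS
    white_metrics: Sequence[str] = WHITE_METRICS
    true_paths: Mapping[str, float] = field(default_factory=dict)
    within_metric_rho: float = 0.30
    cross_metric_rho: float = 0.40
    cross_tissue_rho: float = 0.15
    gmv_composition_noise: float = 0.30
    missing_rate: float = 0.02
    seed: int = 0
    include_tiv: bool = False
    tiv_noise: float = 0.30
    include_sex: bool = False
    female_fraction: float = 0.478

    # -- structure ---------------------------------------------------------

    def region_labels(self) -> list[str]:
        return [f"region{r + 1:02d}" for r in range(self.n_gray_regions)]

    def tract_labels(self) -> list[str]:
        return [f"tract{t + 1:02d}" for t in range(self.n_white_tracts)]

    def feature_names(self) -> list[str]:
        names = []
        for m in self.gray_metrics:
            names += [f"{m}_{r}" for r in self.region_labels()]
        for m in self.white_metrics:
            names += [f"{m}_{t}" for t in self.tract_labels()]
        return names

    @property
    def n_features(self) -> int:
        return len(self.gray_metrics) * self.n_gray_regions + len(self.white_metrics) * self.n_white_tracts

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        L = np.asarray(self.loadings, dtype=float)
        if len(L) != len(self.task_names):
            raise ValueError("loadings and task_names must have equal length")
        if np.any(L <= 0) or np.any(L >= 1):
            raise ValueError("standardized loadings must lie in (0, 1)")
        for name, v, lo, hi in (
            ("within_metric_rho", self.within_metric_rho, 0.0, 1.0),
            ("cross_metric_rho", self.cross_metric_rho, 0.0, 1.0),
            ("cross_tissue_rho", self.cross_tissue_rho, 0.0, 1.0),
        ):
            if not lo <= v < hi:
                raise ValueError(f"{name}={v} must lie in [0, 1)")
        if self.cross_tissue_rho > min(self.within_metric_rho, self.cross_metric_rho):
            raise ValueError(
                "cross-tissue block is not positive definite: cross_tissue_rho must "
                "not exceed within_metric_rho or cross_metric_rho"
            )
        resid = 1.0 - self.within_metric_rho - self.cross_metric_rho + self.cross_tissue_rho
        if resid <= 0:
            raise ValueError(
                "within-metric/within-region block is not positive definite: need "
                "within_metric_rho + cross_metric_rho - cross_tissue_rho < 1"
            )
        if not 0.0 < self.gmv_composition_noise <= 1.0:
            raise ValueError(
                "GMV composition block is singular: gmv_composition_noise must lie in (0, 1]"
            )
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        unknown = set(self.true_paths) - set(self.feature_names())
        if unknown:
            raise ValueError(f"true_paths name unknown features: {sorted(unknown)[:5]}")
        gam = self.path_vector()
        total = float(gam @ self.feature_covariance() @ gam)
        if total >= 1.0:
            raise ValueError(
                f"true_paths explain {total:.3f} of the latent variance; must be < 1"
            )

    def path_vector(self) -> np.ndarray:
        names = self.feature_names()
        gam = np.zeros(len(names))
        for j, name in enumerate(names):
            gam[j] = float(self.true_paths.get(name, 0.0))
        return gam

    # -- population covariance --------------------------------------------

    def _factor_loadings(self):
        """Loading matrix of the base (non-GMV) features on the latent
        correlation factors plus their idiosyncratic SDs."""
        base_metrics = [m for m in list(self.gray_metrics) + list(self.white_metrics) if m != "GMV"]
        regions = {"gray": self.region_labels(), "white": self.tract_labels()}
        cols = []
        for m in base_metrics:
            tissue = "gray" if m in self.gray_metrics else "white"
            cols += [(m, tissue, r) for r in regions[tissue]]
        n_base = len(cols)
        a = np.sqrt(self.cross_tissue_rho)
        c = np.sqrt(self.within_metric_rho - self.cross_tissue_rho)
        d = np.sqrt(self.cross_metric_rho - self.cross_tissue_rho)
        resid = np.sqrt(1.0 - self.within_metric_rho - self.cross_metric_rho + self.cross_tissue_rho)

        metric_ids = {m: i for i, m in enumerate(base_metrics)}
        region_ids = {}
        for tissue in ("gray", "white"):
            for r in regions[tissue]:
                region_ids[(tissue, r)] = len(region_ids)
        n_fact = 1 + len(metric_ids) + len(region_ids)
        Lmat = np.zeros((n_base, n_fact))
        for i, (m, tissue, r) in enumerate(cols):
            Lmat[i, 0] = a
            Lmat[i, 1 + metric_ids[m]] = c
            Lmat[i, 1 + len(metric_ids) + region_ids[(tissue, r)]] = d
        return cols, Lmat, resid

    def feature_covariance(self) -> np.ndarray:
        """Population covariance of all features, GMV composition included.

        All features have unit variance, so this is also the population
        correlation matrix.
        """
        cols, Lmat, resid = self._factor_loadings()
        Sb = Lmat @ Lmat.T
        np.fill_diagonal(Sb, 1.0)
        names = self.feature_names()
        base_index = {f"{m}_{r}": i for i, (m, _, r) in enumerate(cols)}
        has_gmv = "GMV" in self.gray_metrics
        if not has_gmv:
            order = [base_index[n] for n in names]
            return Sb[np.ix_(order, order)]

        tau = self.gmv_composition_noise
        w = np.sqrt((1.0 - tau**2) / (2.0 + 2.0 * self.cross_metric_rho))
        # linear map from base features to the full set
        p = len(names)
        A = np.zeros((p, len(cols)))
        noise_var = np.zeros(p)
        for j, name in enumerate(names):
            metric, _, region = name.partition("_")
            if metric == "GMV":
                A[j, base_index[f"CT_{region}"]] = w
                A[j, base_index[f"SA_{region}"]] = w
                noise_var[j] = tau**2
            else:
                A[j, base_index[name]] = 1.0
        Sigma = A @ Sb @ A.T + np.diag(noise_var)
        return Sigma

    def tiv_profile(self):
        """(covariance of TIV with each feature, SD retained) for the
        common-size composite built from the volume columns."""
        names = self.feature_names()
        Sigma = self.feature_covariance()
        vol = np.array([n.startswith(("GMV_", "WMV_")) for n in names])
        if not vol.any():
            raise ValueError("no volume columns; TIV is undefined for this configuration")
        ones = vol.astype(float)
        raw_var = float(ones @ Sigma @ ones)
        scale = np.sqrt(1.0 - self.tiv_noise**2) / np.sqrt(raw_var)
        cov = scale * (Sigma @ ones)
        return cov, scale, ones


@dataclass
class SyntheticDataset:
    """One realized draw plus its generating truth."""

    cognition: CognitionTable
    brain: BrainFeatureTable
    truth: dict

    def to_csv(self, outdir) -> dict:
        """Write cognition and brain CSVs (NA for missing) plus a JSON truth
        sidecar; returns the file manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cog = outdir / "cognition.csv"
        brn = outdir / "brain_features.csv"
        tru = outdir / "truth.json"
        self.cognition.scores.to_csv(cog, index_label="id", na_rep="NA", float_format="%.17g")
        frame = self.brain.features
        if not self.brain.covariates.empty:
            frame = pd.concat([frame, self.brain.covariates], axis=1)
        frame.to_csv(brn, index_label="id", na_rep="NA", float_format="%.17g")
        record = dict(self.truth)
        record["config"] = asdict_config(record["config"])
        record["latent"] = [float(v) for v in record["latent"]]
        tru.write_text(json.dumps(record, indent=1))
        return {"cognition": str(cog), "brain": str(brn), "truth": str(tru)}


def asdict_config(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["loadings"] = list(map(float, d["loadings"]))
    d["task_names"] = list(d["task_names"])
    d["gray_metrics"] = list(d["gray_metrics"])
    d["white_metrics"] = list(d["white_metrics"])
    d["true_paths"] = {k: float(v) for k, v in d["true_paths"].items()}
    return d


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; bit-identical under a fixed seed.

    Features are sampled through the factor representation of the block
    covariance (so the sample covariance converges to
    ``config.feature_covariance()``); the latent factor is built as
    gamma' x plus a disturbance scaled so its population variance is 1,
    making ``true_paths`` the population standardized effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    names = config.feature_names()

    cols, Lmat, resid = config._factor_loadings()
    n_fact = Lmat.shape[1]
    factors = rng.standard_normal((n, n_fact))
    base = factors @ Lmat.T + resid * rng.standard_normal((n, len(cols)))
    base_index = {f"{m}_{r}": i for i, (m, _, r) in enumerate(cols)}

    tau = config.gmv_composition_noise
    w = np.sqrt((1.0 - tau**2) / (2.0 + 2.0 * config.cross_metric_rho))
    X = np.empty((n, len(names)))
    for j, name in enumerate(names):
        metric, _, region = name.partition("_")
        if metric == "GMV":
            X[:, j] = w * (base[:, base_index[f"CT_{region}"]] + base[:, base_index[f"SA_{region}"]])
            X[:, j] += tau * rng.standard_normal(n)
        else:
            X[:, j] = base[:, base_index[name]]

    gam = config.path_vector()
    Sigma = config.feature_covariance()
    explained = float(gam @ Sigma @ gam)
    eta = X @ gam + np.sqrt(1.0 - explained) * rng.standard_normal(n)

    L = np.asarray(config.loadings, dtype=float)
    Y = eta[:, None] * L + rng.standard_normal((n, len(L))) * np.sqrt(1.0 - L**2)
    if config.missing_rate > 0:
        mask = rng.random(Y.shape) < config.missing_rate
        Y = np.where(mask, np.nan, Y)

    covars = {}
    if config.include_tiv:
        _, scale, ones = config.tiv_profile()
        covars["TIV"] = scale * (X @ ones) + config.tiv_noise * rng.standard_normal(n)
    if config.include_sex:
        covars["sex"] = np.where(rng.random(n) < config.female_fraction, "F", "M")

    cognition = CognitionTable(pd.DataFrame(Y, columns=list(config.task_names)))
    brain = BrainFeatureTable(
        pd.DataFrame(X, columns=names),
        covariates=pd.DataFrame(covars) if covars else pd.DataFrame(index=range(n)),
    )
    truth = {"config": config, "latent": eta, "explained_variance": explained}
    return SyntheticDataset(cognition=cognition, brain=brain, truth=truth)


# --------------------------------------------------------------------------
# closed-form population R-squared oracle
# --------------------------------------------------------------------------


def population_r2(config: SyntheticConfig, subset: Iterable[str]) -> float:
    """Population R-squared of the latent factor on a feature subset.

    Computed in closed form from the block covariance and the true paths:
    with c = Cov(x_S, eta) and the subset covariance Sigma_SS, the best
    linear predictor explains c' Sigma_SS^-1 c of the unit latent
    variance.  Accepts the name ``"TIV"`` when the configuration includes
    a TIV composite.  Monotone nondecreasing under superset inclusion.
    """
    subset = list(subset)
    if not subset:
        return 0.0
    names = config.feature_names()
    index = {n: j for j, n in enumerate(names)}
    Sigma = config.feature_covariance()
    gam = config.path_vector()
    cov_eta = Sigma @ gam  # Cov(x, eta); disturbance is independent of x

    want_tiv = "TIV" in subset
    if want_tiv:
        tiv_cov, scale, ones = config.tiv_profile()
        Sigma = np.block(
            [[Sigma, tiv_cov[:, None]], [tiv_cov[None, :], np.array([[1.0]])]]
        )
        cov_eta = np.append(cov_eta, scale * float(ones @ (config.feature_covariance() @ gam)))
        index["TIV"] = len(names)

    try:
        idx = [index[s] for s in subset]
    except KeyError as exc:
        raise KeyError(f"unknown predictor name {exc.args[0]!r}") from None
    Sss = Sigma[np.ix_(idx, idx)]
    c = cov_eta[idx]
    r2 = float(c @ np.linalg.solve(Sss, c))
    return float(min(max(r2, 0.0), 1.0))


# --------------------------------------------------------------------------
# study-condition configurations
# --------------------------------------------------------------------------


def _signal_template(config: SyntheticConfig):
    """Sparse unscaled effect patterns per tissue, mirroring a study in
    which area and volume dominate gray-matter prediction (thickness weak,
    one region slightly negative) and tract volume dominates white-matter
    prediction over FA and MD."""
    regions = config.region_labels()
    tracts = config.tract_labels()
    gray = {}
    for r in regions[0:4]:
        gray[f"SA_{r}"] = 0.065
    for r in regions[4:8]:
        gray[f"GMV_{r}"] = 0.065
    for r in regions[8:11]:
        gray[f"CT_{r}"] = 0.030
    gray[f"CT_{regions[11]}"] = -0.018
    white = {}
    for t in tracts[0:3]:
        white[f"WMV_{t}"] = 0.075
    for t in tracts[3:5]:
        white[f"FA_{t}"] = 0.035
    for t in tracts[5:7]:
        white[f"MD_{t}"] = -0.022
    return gray, white


def partial_overlap_config(
    n_participants: int = 12000,
    seed: int = 0,
    r2_gray: float = 0.154,
    r2_white: float = 0.124,
    r2_joint: float = 0.190,
    missing_rate: float = 0.02,
    include_tiv: bool = False,
    include_sex: bool = False,
    r2_tiv: float | None = 0.068,
) -> SyntheticConfig:
    """Partial-overlap study conditions calibrated by the closed-form oracle.

    Scales the two tissue signal patterns and the cross-tissue correlation
    so that the population R-squared of the latent factor on the gray-only,
    white-only and combined feature sets matches the requested triple
    (defaults reproduce a partially-overlapping variance partition).  When
    TIV is included, its composite noise is additionally tuned so the
    TIV-only population R-squared matches ``r2_tiv`` where attainable.
    """
    base = SyntheticConfig(n_participants=n_participants, seed=seed, missing_rate=missing_rate)
    gray_t, white_t = _signal_template(base)
    gray_cols = [n for n in base.feature_names() if n.split("_")[0] in base.gray_metrics]
    white_cols = [n for n in base.feature_names() if n.split("_")[0] in base.white_metrics]

    def build(sg: float, sw: float, rho_ct: float) -> SyntheticConfig:
        paths = {k: sg * v for k, v in gray_t.items()}
        paths.update({k: sw * v for k, v in white_t.items()})
        return SyntheticConfig(
            n_participants=n_participants,
            seed=seed,
            missing_rate=missing_rate,
            true_paths=paths,
            cross_tissue_rho=rho_ct,
            include_tiv=include_tiv,
            include_sex=include_sex,
        )

    def residuals(z):
        sg, sw, rho = z
        cfg = build(sg, sw, rho)
        return [
            population_r2(cfg, gray_cols) - r2_gray,
            population_r2(cfg, white_cols) - r2_white,
            population_r2(cfg, gray_cols + white_cols) - r2_joint,
        ]

    sol = optimize.least_squares(
        residuals,
        x0=[1.0, 1.2, 0.15],
        bounds=([0.05, 0.05, 0.0], [4.0, 4.0, 0.29]),
        xtol=1e-12,
        ftol=1e-12,
    )
    sg, sw, rho = sol.x
    cfg = build(float(sg), float(sw), float(rho))
    cfg.validate()

    if include_tiv and r2_tiv is not None:
        # R2_TIV is monotone decreasing in the composite noise
        def tiv_gap(tau):
            cfg.tiv_noise = tau
            return population_r2(cfg, ["TIV"]) - r2_tiv

        lo, hi = 0.02, 0.995
        if tiv_gap(lo) > 0 > tiv_gap(hi):
            cfg.tiv_noise = float(optimize.brentq(tiv_gap, lo, hi, xtol=1e-6))
        else:  # target unattainable for this signal pattern; keep strongest
            cfg.tiv_noise = lo
    return cfg


def redundant_config(n_participants: int = 12000, seed: int = 0, **kw) -> SyntheticConfig:
    """Conditions in which the white-matter features relay the same
    information as gray matter: only gray features carry direct paths, and
    high cross-tissue correlation lets white features proxy them."""
    base = SyntheticConfig(
        n_participants=n_participants,
        seed=seed,
        within_metric_rho=0.45,
        cross_metric_rho=0.46,
        cross_tissue_rho=0.44,
        **kw,
    )
    gray_t, _ = _signal_template(base)
    base.true_paths = {k: 1.2 * v for k, v in gray_t.items()}
    base.validate()
    return base


def independent_config(n_participants: int = 12000, seed: int = 0, **kw) -> SyntheticConfig:
    """Conditions with zero cross-tissue correlation and disjoint signal,
    making the two tissues' contributions additive."""
    base = SyntheticConfig(
        n_participants=n_participants, seed=seed, cross_tissue_rho=0.0, **kw
    )
    gray_t, white_t = _signal_template(base)
    base.true_paths = {**gray_t, **white_t}
    base.validate()
    return base
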