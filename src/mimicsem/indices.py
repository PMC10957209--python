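"""Model-evaluation quantities: chi-square, RMSEA, CFI/TLI, SRMR, AIC/BIC,
likelihood-ratio tests, and latent-outcome (adjusted) R-squared.

Conventions: the chi-square statistic is N * F_min (N the analysis sample
size); with missing data it is computed as twice the log-likelihood gap to
an EM-estimated saturated model.  The incremental-fit baseline is the
independence model (all covariances zero, variances and means free).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .model import (
    MimicModelSpec,
    MomentSummary,
    ParameterEstimates,
    sample_moments,
    em_saturated_moments,
)


@dataclass
class FitIndexSet:
    """One model's fit summary, one CSV row per model."""

    chi2: float
    df: int
    p_value: float
    rmsea: float
    rmsea_lo: float
    rmsea_hi: float
    cfi: float
    tli: float
    srmr: float
    aic: float
    bic: float
    r2: float
    r2_adj: float
    n_obs: int
    n_free: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def chi_square(f_min: float, n_obs: int) -> float:
    """Likelihood-ratio test statistic N * F_min."""
    if f_min < 0:
        raise ValueError("F_min must be nonnegative")
    return float(n_obs) * float(f_min)


def model_df(spec: MimicModelSpec) -> int:
    """Degrees of freedom: nonredundant moments minus free parameters.

    Mean parameters are saturated and cancel, so only the covariance
    structure counts.  A 5-indicator single-factor model has 15 - 10 = 5.
    """
    q = len(spec.indicators)
    p = len(spec.predictors)
    m = q + p
    moments = m * (m + 1) // 2
    free = spec.n_free_conditional(include_means=False) + p * (p + 1) // 2
    df = moments - free
    if df < 0:
        raise ValueError(f"model is over-parameterized: df = {df}")
    return df


def rmsea(chi2_val: float, df: int, n_obs: int, ci_level: float = 0.90):
    """Root-mean-square error of approximation with a noncentral-chi2 CI.

    Point estimate sqrt(max(chi2 - df, 0) / (df * N)); the CI endpoints
    invert the noncentral chi-square distribution for the noncentrality
    parameter.
    """
    if df < 1:
        raise ValueError("RMSEA is undefined for df = 0")
    n = float(n_obs)
    point = float(np.sqrt(max(chi2_val - df, 0.0) / (df * n)))
    alpha = 1.0 - ci_level

    def _ncp(prob):
        # lambda such that P(X_{df,lambda} <= chi2) = prob
        f = lambda lam: sps.ncx2.cdf(chi2_val, df, lam) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(10.0, 2.0 * chi2_val)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2.0
        return brentq(f, 0.0, hi, xtol=1e-8)

    lam_lo = _ncp(1.0 - alpha / 2.0)  # lower endpoint: larger cdf value
    lam_hi = _ncp(alpha / 2.0)
    lo = float(np.sqrt(lam_lo / (df * n)))
    hi = float(np.sqrt(lam_hi / (df * n)))
    return point, (lo, hi)


def cfi_tli(chi2_val: float, df: int, chi2_baseline: float, df_baseline: int):
    """Comparative fit index and Tucker-Lewis index against the
    independence baseline.  CFI is clamped to [0, 1]; TLI may exceed 1."""
    if df_baseline < df:
        raise ValueError("baseline df must be at least the target df")
    d_t = max(chi2_val - df, 0.0)
    d_b = max(chi2_baseline - df_baseline, d_t, 0.0)
    if chi2_baseline - df_baseline < chi2_val - df:
        warnings.warn("baseline model fits better than the target model; CFI clamped")
    cfi = 1.0 if d_b == 0.0 else 1.0 - d_t / d_b
    cfi = float(min(max(cfi, 0.0), 1.0))
    denom = chi2_baseline / df_baseline - 1.0
    if denom == 0.0:
        tli = 1.0
    else:
        tli = float((chi2_baseline / df_baseline - chi2_val / df) / denom)
    return cfi, tli


def srmr(S, sigma_hat) -> float:
    """Root mean squared standardized residual over the lower triangle
    (diagonal included; each matrix is standardized by its own SDs)."""
    Smat = S.S if isinstance(S, MomentSummary) else np.asarray(S, dtype=float)
    Sig = np.asarray(sigma_hat, dtype=float)
    if Smat.shape != Sig.shape:
        raise ValueError("dimension mismatch")
    ds = np.sqrt(np.diag(Smat))
    dm = np.sqrt(np.diag(Sig))
    if np.any(ds <= 0) or np.any(dm <= 0):
        raise ValueError("zero variance on a diagonal; cannot standardize residuals")
    Rs = Smat / np.outer(ds, ds)
    Rm = Sig / np.outer(dm, dm)
    idx = np.tril_indices_from(Smat)
    resid = (Rs - Rm)[idx]
    return float(np.sqrt(np.mean(resid**2)))


def information_criteria(loglik: float, n_free: int, n_obs: int):
    """AIC = -2l + 2k and BIC = -2l + k ln(n)."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    aic = -2.0 * loglik + 2.0 * n_free
    bic = -2.0 * loglik + n_free * float(np.log(n_obs))
    return float(aic), float(bic)


def latent_r2(est: ParameterEstimates, spec: MimicModelSpec | None = None, n_obs: int | None = None):
    """Proportion of latent-factor variance explained by the predictors.

    R2 = 1 - psi / Var(eta); the adjustment uses the number of predictor
    paths k: 1 - (1 - R2)(n - 1)/(n - k - 1).
    """
    spec = spec or est.spec
    n = est.n_obs if n_obs is None else n_obs
    if not len(spec.predictors):
        raise ValueError("R-squared is undefined for a pure CFA (no predictors)")
    fvar = est.factor_variance
    r2 = float(1.0 - est.psi / fvar)
    k = sum(1 for p in spec.predictors if spec.fixed.get(f"gamma:{p}", None) != 0.0)
    r2_adj = float(1.0 - (1.0 - r2) * (n - 1) / (n - k - 1))
    return r2, r2_adj


def likelihood_ratio_test(free: ParameterEstimates, constrained: ParameterEstimates):
    """Chi-square difference test of a constrained model nested in a free one.

    Returns ``(delta_chi2, delta_df, p)``; a negative difference beyond
    numerical tolerance triggers a warning and is clamped at 0.
    """
    if set(free.spec.indicators) != set(constrained.spec.indicators) or set(
        free.spec.predictors
    ) != set(constrained.spec.predictors):
        raise ValueError("models are not nested: variable sets differ")
    delta_df = free.n_free - constrained.n_free
    if delta_df < 0:
        raise ValueError("constrained model has more free parameters than the free model")
    delta = 2.0 * (free.loglik - constrained.loglik)
    if delta < -1e-6:
        warnings.warn(f"negative chi-square difference ({delta:.3g}) clamped to 0")
    delta = max(delta, 0.0)
    if delta_df == 0:
        return delta, 0, 1.0
    p = float(sps.chi2.sf(delta, delta_df))
    return float(delta), int(delta_df), p


# --------------------------------------------------------------------------
# convenience: full index set for a fitted model
# --------------------------------------------------------------------------


def _baseline_chi2(S: np.ndarray, n: int):
    """Independence-model chi-square: N * (-ln det R)."""
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    _, logdet = np.linalg.slogdet(R)
    p = S.shape[0]
    return float(-n * logdet), p * (p + 1) // 2 - p


def fit_index_set(data: pd.DataFrame, spec: MimicModelSpec, est: ParameterEstimates) -> FitIndexSet:
    """Assemble every index for one fitted model.

    With missing indicator entries, chi-square comes from the FIML
    log-likelihood difference to the EM-saturated model, and the sample
    moments entering SRMR and the baseline are the EM estimates.
    """
    from .model import implied_moments  # local to avoid cycle at import time

    names = list(spec.indicators) + list(spec.predictors)
    n = est.n_obs
    if est.loglik_saturated is None:
        raise ValueError("estimates carry no saturated log-likelihood; refit with compute_saturated=True")
    chi2_val = max(2.0 * (est.loglik_saturated - est.loglik), 0.0)
    df = model_df(spec)

    frame = data[names]
    if est.method == "ml_complete" or not frame.isna().to_numpy().any():
        mom = sample_moments(frame, names)
        S = mom.S
    else:
        _, S, _, _ = em_saturated_moments(frame, names)

    chi2_b, df_b = _baseline_chi2(S, n)
    Sigma, _ = implied_moments(spec, est.raw, est.predictor_cov, est.predictor_means)

    if df >= 1:
        point, (lo, hi) = rmsea(chi2_val, df, n)
        p_value = float(sps.chi2.sf(chi2_val, df))
    else:
        point, lo, hi = 0.0, 0.0, 0.0
        p_value = 1.0
    cfi, tli = cfi_tli(chi2_val, max(df, 1), chi2_b, max(df_b, 1)) if df >= 1 else (1.0, 1.0)
    aic, bic = information_criteria(est.loglik, est.n_free, n)
    if len(spec.predictors):
        r2, r2_adj = latent_r2(est, spec)
    else:
        r2, r2_adj = np.nan, np.nan
    return FitIndexSet(
        chi2=chi2_val,
        df=df,
        p_value=p_value,
        rmsea=point,
        rmsea_lo=lo,
        rmsea_hi=hi,
        cfi=cfi,
        tli=tli,
        srmr=srmr(S, Sigma),
        aic=aic,
        bic=bic,
        r2=r2,
        r2_adj=r2_adj,
        n_obs=n,
        n_free=est.n_free,
    )
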