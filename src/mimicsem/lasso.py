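"""Lasso-penalized MIMIC estimation over a penalty path.

The penalized objective is the ML discrepancy plus an L1 penalty on the
structural paths only,

    F_ML(lambda, theta, psi, gamma) + lambda_pen * sum_j |gamma_j|,

minimized by block coordinate descent: measurement parameters (loadings,
residual variances, latent disturbance) take smooth quasi-Newton steps
while the paths are updated by exact coordinate-wise soft-thresholding,
so zeros in the solution are exact, not thresholded.  Missing indicator
entries are handled by first estimating saturated moments with EM
(FIML-consistent) and then fitting the penalized model to those moments.

Predictors must be standardized to unit variance before penalized fitting
(the lasso is scale-dependent); unstandardized input is refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as _m
from .model import MimicModelSpec, ParameterEstimates, _ParamMap, _cond_nll_grad, _stats_from_moments
from scipy import optimize

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class RegularizationPath:
    """Solution path over a descending penalty grid with BIC selection."""

    lambda_grid: np.ndarray
    estimates: list
    bic: np.ndarray
    loglik: np.ndarray
    n_nonzero: np.ndarray
    selected_index: int
    predictor_names: list[str]

    @property
    def selected(self) -> ParameterEstimates:
        return self.estimates[self.selected_index]

    @property
    def surviving(self) -> list[str]:
        est = self.selected
        return [p for j, p in enumerate(self.predictor_names) if est.gamma[j] != 0.0]

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (lambda, predictor) with survival flag."""
        rows = []
        for i, lam in enumerate(self.lambda_grid):
            g = self.estimates[i].gamma
            for j, pred in enumerate(self.predictor_names):
                rows.append(
                    {
                        "lambda": lam,
                        "predictor": pred,
                        "estimate": g[j],
                        "survives": bool(g[j] != 0.0),
                        "selected": i == self.selected_index,
                    }
                )
        return pd.DataFrame(rows)

    def selection_summary(self) -> dict:
        return {
            "lambda_selected": float(self.lambda_grid[self.selected_index]),
            "selected_index": int(self.selected_index),
            "n_surviving": int(self.n_nonzero[self.selected_index]),
            "surviving": self.surviving,
            "bic_selected": float(self.bic[self.selected_index]),
        }


# --------------------------------------------------------------------------
# moments preparation
# --------------------------------------------------------------------------


def _penalized_moments(data: pd.DataFrame, spec: MimicModelSpec):
    """Centered joint moments of (indicators, predictors), via EM when
    indicator entries are missing.  Returns (S, n)."""
    names = list(spec.indicators) + list(spec.predictors)
    frame = data[names]
    if frame[spec.predictors].isna().to_numpy().any():
        raise ValueError("predictors contain missing values")
    if frame[spec.indicators].isna().to_numpy().any():
        _, S, _, n = _m.em_saturated_moments(frame, names)
    else:
        mom = _m.sample_moments(frame, names)
        S, n = mom.S, mom.n_obs
    return S, int(n)


def _check_standardized(S: np.ndarray, q: int, names, tol: float = 0.1) -> None:
    v = np.diag(S)[q:]
    bad = [n for n, vi in zip(names, v) if abs(vi - 1.0) > tol]
    if bad:
        raise ValueError(
            "predictors must be standardized to unit variance before penalized "
            f"fitting (off by more than {tol}: {bad[:5]}{'...' if len(bad) > 5 else ''}); "
            "apply mimicsem.standardize_columns first"
        )


# --------------------------------------------------------------------------
# inner solvers
# --------------------------------------------------------------------------


def _measurement_step(S, q, n, gam, lam, the, psi, spec, maxiter=200):
    """Minimize the smooth part over (lam, theta, psi) with gamma fixed.

    Collapses the predictors into the single composite c = gamma'x, which
    leaves a (q+1)-variable problem independent of p.
    """
    Syy = S[:q, :q]
    Syx = S[:q, q:]
    Sxx = S[q:, q:]
    scc = float(gam @ Sxx @ gam)
    syc = Syx @ gam
    Sred = np.empty((q + 1, q + 1))
    Sred[:q, :q] = Syy
    Sred[:q, q] = syc
    Sred[q, :q] = syc
    Sred[q, q] = max(scc, 1e-12)
    pseudo = MimicModelSpec(
        spec.indicators,
        ["_composite"],
        fixed={**{k: v for k, v in spec.fixed.items() if not k.startswith("gamma:")}, "gamma:_composite": 1.0},
        meanstructure=False,
    )
    pm = _ParamMap(pseudo, include_means=False)
    stats = _stats_from_moments(Sred, q, n)
    u0 = pm.pack(np.zeros(q), lam, np.array([1.0]), the, psi)
    res = optimize.minimize(
        _cond_nll_grad, u0, args=(pm, stats), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": 1e-8, "ftol": 1e-14},
    )
    _, lam2, _, the2, psi2 = pm.unpack(res.x)
    return lam2, the2, psi2, float(res.fun)


def _cd_sweeps(g, v, Sxx, d, b_a, thr_a, free, max_sweeps, tol):
    """Soft-thresholded coordinate sweeps on g in place; returns sweeps used."""
    p = g.shape[0]
    for sweep in range(max_sweeps):
        delta_max = 0.0
        for j in range(p):
            if not free[j]:
                continue
            rj = b_a[j] - (v[j] - d[j] * g[j])
            arj = abs(rj) - thr_a
            gj_new = (arj / d[j]) * (1.0 if rj > 0 else -1.0) if arj > 0.0 else 0.0
            dg = gj_new - g[j]
            if dg != 0.0:
                g[j] = gj_new
                for k in range(p):
                    v[k] += dg * Sxx[k, j]
                if abs(dg) > delta_max:
                    delta_max = abs(dg)
        if delta_max < tol:
            return sweep + 1
    return max_sweeps


try:  # JIT the inner kernel when numba is around; the fallback is identical
    from numba import njit as _njit

    _cd_sweeps = _njit(cache=True)(_cd_sweeps)
except ImportError:  # pragma: no cover
    pass


def _gamma_cd(S, q, gam, lam, the, psi, lambda_pen, free_mask, max_sweeps=200, tol=1e-9):
    """Exact coordinate descent for the paths given the measurement model.

    Solves min_g a g'Sxx g - 2 b'g + lambda_pen ||g||_1 with
    a = lam' W lam and b = Sxy W lam (W the inverse conditional indicator
    covariance); coordinate updates are soft-thresholded, giving exact
    zeros.
    """
    Sxx = np.ascontiguousarray(S[q:, q:])
    Syx = S[:q, q:]
    V = psi * np.outer(lam, lam) + np.diag(the)
    W = np.linalg.inv(V)
    Wl = W @ lam
    a = float(lam @ Wl)
    b = Syx.T @ Wl
    g = gam.copy()
    v = Sxx @ g  # running Sxx @ gamma
    d = np.ascontiguousarray(np.diag(Sxx))
    _cd_sweeps(g, v, Sxx, d, np.ascontiguousarray(b / a), lambda_pen / (2.0 * a),
               free_mask.astype(np.bool_), max_sweeps, tol)
    return g


def _conditional_nll_moments(S, q, n, lam, the, psi, gam):
    """n/2 * (q ln 2pi + ln|V| + tr(W M)) on centered moments."""
    V = psi * np.outer(lam, lam) + np.diag(the)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    W = np.linalg.inv(V)
    Syy, Syx, Sxx = S[:q, :q], S[:q, q:], S[q:, q:]
    B = np.outer(lam, gam)
    M = Syy - Syx @ B.T - B @ Syx.T + B @ Sxx @ B.T
    return 0.5 * n * (q * _LOG2PI + logdet + float(np.sum(W * M)))


# --------------------------------------------------------------------------
# public fits
# --------------------------------------------------------------------------


def _fit_lasso_moments(S, q, n, spec, lambda_pen, init=None, max_outer=200, tol=1e-7):
    p = S.shape[0] - q
    free_mask = np.array(
        [f"gamma:{pred}" not in spec.fixed for pred in spec.predictors], dtype=bool
    )
    fixed_vals = np.array(
        [spec.fixed.get(f"gamma:{pred}", 0.0) for pred in spec.predictors], dtype=float
    )
    if init is not None:
        lam, the, psi, gam = (x.copy() if hasattr(x, "copy") else x for x in init)
        gam = np.where(free_mask, gam, fixed_vals)
    else:
        gam = np.where(free_mask, 0.0, fixed_vals)
        pm0 = _ParamMap(spec, include_means=False)
        w, Vv = np.linalg.eigh(S[:q, :q])
        vref = Vv[:, -1] / (Vv[0, -1] if abs(Vv[0, -1]) > 1e-8 else 1.0)
        lam = np.where(np.isnan(pm0.lam_fixed), vref, pm0.lam_fixed)
        the = np.maximum(0.5 * np.diag(S[:q, :q]), 1e-3)
        the = np.where(np.isnan(pm0.theta_fixed), the, pm0.theta_fixed)
        psi = 0.5 * float(np.diag(S[:q, :q]).mean())

    prev = None
    converged = False
    for it in range(max_outer):
        lam, the, psi, _ = _measurement_step(S, q, n, gam, lam, the, psi, spec)
        gam = _gamma_cd(S, q, gam, lam, the, psi, lambda_pen, free_mask)
        cur = np.concatenate([lam, the, [psi], gam])
        if prev is not None and np.max(np.abs(cur - prev)) < tol:
            converged = True
            break
        prev = cur
    if not converged and max_outer > 1:
        warnings.warn(
            f"penalized fit did not fully stabilize after {max_outer} outer iterations "
            f"(lambda={lambda_pen:.4g})"
        )

    cond_nll = _conditional_nll_moments(S, q, n, lam, the, psi, gam)
    Sxx = S[q:, q:]
    ll = -cond_nll + _m._x_block_loglik(Sxx, n)
    nnz = int(np.count_nonzero(gam[free_mask]))
    pm0 = _ParamMap(spec, include_means=False)
    n_meas_free = pm0.n_free - len(pm0.gamma_slots)
    n_free = n_meas_free + nnz + p * (p + 1) // 2

    raw = {}
    for k, task in enumerate(spec.indicators):
        raw[f"lambda:{task}"] = float(lam[k])
        raw[f"theta:{task}"] = float(the[k])
    for j, pred in enumerate(spec.predictors):
        raw[f"gamma:{pred}"] = float(gam[j])
    raw["psi"] = float(psi)
    est = ParameterEstimates(
        raw=raw,
        standardized={},
        loglik=float(ll),
        n_obs=n,
        converged=bool(converged or max_outer == 1),
        n_free=n_free,
        spec=spec,
        method="lasso",
        nu=np.zeros(q),
        lam=lam.copy(),
        gamma=gam.copy(),
        theta=the.copy(),
        psi=float(psi),
        predictor_cov=Sxx,
        predictor_means=np.zeros(p),
        loglik_conditional=float(-cond_nll),
        n_iter=it + 1,
    )
    est.standardized = _m._standardized_map(est)
    est.lambda_pen = float(lambda_pen)
    return est


def fit_lasso(
    data: pd.DataFrame,
    spec: MimicModelSpec,
    lambda_pen: float,
    init=None,
    max_outer: int = 200,
) -> ParameterEstimates:
    """One penalized fit at a fixed penalty weight.

    At ``lambda_pen=0`` this reproduces the unpenalized ML fit; at or above
    the null-gradient bound ``lambda_max`` every penalized path is exactly
    zero.
    """
    if lambda_pen < 0:
        raise ValueError("lambda_pen must be nonnegative")
    S, n = _penalized_moments(data, spec)
    _check_standardized(S, len(spec.indicators), spec.predictors)
    return _fit_lasso_moments(S, len(spec.indicators), n, spec, lambda_pen, init=init, max_outer=max_outer)


def lambda_max(data: pd.DataFrame, spec: MimicModelSpec) -> float:
    """Smallest penalty at which the all-zero path solution is stationary,
    from the gradient of the discrepancy at the null (CFA) model."""
    S, n = _penalized_moments(data, spec)
    return _lambda_max_moments(S, len(spec.indicators), n, spec)


def _lambda_max_moments(S, q, n, spec) -> float:
    free_mask = np.array([f"gamma:{p}" not in spec.fixed for p in spec.predictors], dtype=bool)
    gam0 = np.array([spec.fixed.get(f"gamma:{p}", 0.0) for p in spec.predictors], dtype=float)
    pm0 = _ParamMap(spec, include_means=False)
    lam = np.where(np.isnan(pm0.lam_fixed), 1.0, pm0.lam_fixed)
    the = np.maximum(0.5 * np.diag(S[:q, :q]), 1e-3)
    the = np.where(np.isnan(pm0.theta_fixed), the, pm0.theta_fixed)
    psi = 0.5 * float(np.diag(S[:q, :q]).mean())
    lam, the, psi, _ = _measurement_step(S, q, n, gam0, lam, the, psi, spec)
    V = psi * np.outer(lam, lam) + np.diag(the)
    Wl = np.linalg.solve(V, lam)
    a = float(lam @ Wl)
    b = S[:q, q:].T @ Wl
    # account for fixed nonzero paths through the running residual
    v = S[q:, q:] @ gam0
    grad0 = 2.0 * (a * v - b)
    vals = np.abs(grad0[free_mask])
    return float(vals.max()) if vals.size else 0.0


def fit_path(
    data: pd.DataFrame,
    spec: MimicModelSpec,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-3,
) -> RegularizationPath:
    """Warm-started solution path from lambda_max down, selected by BIC.

    The BIC at each grid point uses the log-likelihood of the active set
    refitted without shrinkage (the relaxed-lasso convention), with the
    parameter count including only the nonzero paths; ``path.loglik``
    stores these refit log-likelihoods.
    """
    S, n = _penalized_moments(data, spec)
    q = len(spec.indicators)
    _check_standardized(S, q, spec.predictors)
    lmax = _lambda_max_moments(S, q, n, spec)
    if lmax <= 0:
        raise ValueError("no free penalized paths in this model")
    # nudge the endpoint above the stationarity bound so the sparsest grid
    # point is exactly the all-zero solution despite round-off
    grid = np.geomspace(lmax * (1.0 + 1e-3), lmax * lambda_min_ratio, n_lambda)

    estimates, bics, lls, nnzs = [], [], [], []
    init = None
    failures = 0
    refit_cache: dict[frozenset, float] = {}
    for lam_pen in grid:
        try:
            est = _fit_lasso_moments(S, q, n, spec, lam_pen, init=init)
        except Exception as exc:  # pragma: no cover - defensive path
            failures += 1
            warnings.warn(f"penalized fit failed at lambda={lam_pen:.4g}: {exc}")
            estimates.append(None)
            bics.append(np.inf)
            lls.append(-np.inf)
            nnzs.append(-1)
            continue
        init = (est.lam, est.theta, est.psi, est.gamma)
        estimates.append(est)
        nnzs.append(int(np.count_nonzero(est.gamma)))
        # relaxed BIC: the likelihood of the active set refitted without
        # shrinkage, so sparser solutions are not penalized for bias
        active = frozenset(p for j, p in enumerate(spec.predictors) if est.gamma[j] != 0.0)
        if active not in refit_cache:
            zeros = [p for p in spec.predictors if p not in active]
            refit = _fit_lasso_moments(
                S, q, n, spec.with_paths_fixed_to_zero(zeros), 0.0,
                init=(est.lam, est.theta, est.psi, est.gamma), max_outer=100,
            )
            refit_cache[active] = refit.loglik
        ll = refit_cache[active]
        lls.append(ll)
        _, bic = _m_information_criteria(ll, est.n_free, n)
        bics.append(bic)
    if failures == len(grid):
        raise RuntimeError("every penalized fit along the path failed")
    sel = int(np.argmin(bics))
    return RegularizationPath(
        lambda_grid=grid,
        estimates=estimates,
        bic=np.asarray(bics),
        loglik=np.asarray(lls),
        n_nonzero=np.asarray(nnzs),
        selected_index=sel,
        predictor_names=list(spec.predictors),
    )


def _m_information_criteria(loglik, n_free, n_obs):
    aic = -2.0 * loglik + 2.0 * n_free
    bic = -2.0 * loglik + n_free * float(np.log(n_obs))
    return aic, bic
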