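"""Single-factor CFA and MIMIC structural equation models.

The model: five observed task scores y load on one latent factor eta
(first loading fixed to 1 for identification, factor disturbance variance
free); brain features x enter as observed causes of the factor,

    y_k = nu_k + lambda_k * eta + eps_k,   eps_k ~ N(0, theta_k)
    eta  = sum_j gamma_j x_j + zeta,       zeta  ~ N(0, psi)

with the predictor block saturated (its covariance and means freely
estimated, hence equal to their sample moments at the MLE).  Because
missingness is confined to the indicators, the joint likelihood factorizes
into a saturated marginal for x and a conditional Gaussian for y given x
with mean ``nu + lambda * (gamma' x)`` and covariance
``psi * lambda lambda' + diag(theta)``.  Estimation therefore runs a
quasi-Newton optimizer over the low-dimensional conditional model, using
per-missingness-pattern sufficient statistics, which is exactly
full-information maximum likelihood for the joint model.

Parameter naming convention used in all estimate dictionaries:
``lambda:<task>``, ``nu:<task>``, ``theta:<task>`` (indicator residual
variance), ``gamma:<feature>`` (structural path), ``psi`` (latent
disturbance variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

_LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------


@dataclass
class MimicModelSpec:
    """Symbolic description of one CFA/MIMIC model.

    Parameters
    ----------
    indicators
        Ordered names of the factor indicators (the five cognitive tasks).
        The first indicator's loading is fixed to 1 unless overridden via
        ``fixed``.
    predictors
        Ordered names of observed causes of the latent factor.  Empty for a
        pure CFA.
    equality_groups
        Optional list of groups of predictor names whose paths are
        constrained equal (each group shares one free parameter).
    fixed
        Map from parameter name (see module docstring for the naming
        convention) to a fixed value, e.g. ``{"gamma:CT_insula": 0.0}``.
    meanstructure
        Whether indicator intercepts are modeled.  They are saturated and
        do not affect fit statistics; FIML fits always estimate them.
    """

    indicators: Sequence[str]
    predictors: Sequence[str] = ()
    equality_groups: Sequence[Sequence[str]] | None = None
    fixed: Mapping[str, float] = field(default_factory=dict)
    meanstructure: bool = True

    def __post_init__(self) -> None:
        self.indicators = list(self.indicators)
        self.predictors = list(self.predictors)
        names = self.indicators + self.predictors
        if len(set(names)) != len(names):
            raise ValueError("indicator/predictor names must be unique")
        if not self.indicators:
            raise ValueError("at least one indicator is required")
        if self.equality_groups:
            flat = [p for g in self.equality_groups for p in g]
            if len(set(flat)) != len(flat):
                raise ValueError("equality groups must be disjoint")
            unknown = set(flat) - set(self.predictors)
            if unknown:
                raise ValueError(f"equality groups name unknown predictors: {sorted(unknown)}")

    # -- derived structure -------------------------------------------------

    @property
    def reference_indicator(self) -> str:
        return self.indicators[0]

    def loading_fixed_value(self, task: str) -> float | None:
        key = f"lambda:{task}"
        if key in self.fixed:
            return float(self.fixed[key])
        if task == self.reference_indicator:
            return 1.0
        return None

    def with_paths_fixed_to_zero(self, predictors: Iterable[str]) -> "MimicModelSpec":
        """Nested spec with the given structural paths constrained to 0."""
        fixed = dict(self.fixed)
        for p in predictors:
            if p not in self.predictors:
                raise ValueError(f"{p!r} is not a predictor of this model")
            fixed[f"gamma:{p}"] = 0.0
        return MimicModelSpec(
            self.indicators, self.predictors, self.equality_groups, fixed, self.meanstructure
        )

    def with_equal_paths(self) -> "MimicModelSpec":
        """Spec with every free structural path constrained equal."""
        free = [p for p in self.predictors if f"gamma:{p}" not in self.fixed]
        if len(free) < 2:
            raise ValueError("equality constraint needs at least two free paths")
        return MimicModelSpec(self.indicators, self.predictors, [free], self.fixed, self.meanstructure)

    def free_parameter_names(self, include_means: bool | None = None) -> list[str]:
        return _ParamMap(self, include_means=include_means).names

    def n_free_conditional(self, include_means: bool = False) -> int:
        return len(_ParamMap(self, include_means=include_means).names)


# --------------------------------------------------------------------------
# parameter bookkeeping
# --------------------------------------------------------------------------


class _ParamMap:
    """Maps the free-parameter vector to (nu, lam, gamma, theta, psi).

    Variances are optimized on the log scale, which enforces positivity
    without explicit bounds.  Equality-constrained paths share one entry.
    """

    def __init__(self, spec: MimicModelSpec, include_means: bool | None = None):
        self.spec = spec
        self.q = len(spec.indicators)
        self.p = len(spec.predictors)
        self.include_means = spec.meanstructure if include_means is None else include_means

        self.lam_fixed = np.full(self.q, np.nan)
        for k, task in enumerate(spec.indicators):
            v = spec.loading_fixed_value(task)
            if v is not None:
                self.lam_fixed[k] = v
        self.lam_free_idx = np.flatnonzero(np.isnan(self.lam_fixed))

        self.theta_fixed = np.full(self.q, np.nan)
        for k, task in enumerate(spec.indicators):
            key = f"theta:{task}"
            if key in spec.fixed:
                self.theta_fixed[k] = float(spec.fixed[key])
        self.theta_free_idx = np.flatnonzero(np.isnan(self.theta_fixed))

        self.psi_fixed = float(spec.fixed["psi"]) if "psi" in spec.fixed else None

        # gamma: fixed values, then equality groups, then singletons
        self.gamma_fixed = np.full(self.p, np.nan)
        for j, pred in enumerate(spec.predictors):
            key = f"gamma:{pred}"
            if key in spec.fixed:
                self.gamma_fixed[j] = float(spec.fixed[key])
        group_of = {}
        if spec.equality_groups:
            for gi, group in enumerate(spec.equality_groups):
                for pred in group:
                    group_of[pred] = gi
        # one free slot per equality group, one per untied free path
        self.gamma_slots: list[list[int]] = []
        self.gamma_slot_names: list[str] = []
        seen_groups: dict[int, int] = {}
        for j, pred in enumerate(spec.predictors):
            if not np.isnan(self.gamma_fixed[j]):
                if pred in group_of:
                    raise ValueError(f"path gamma:{pred} is both fixed and equality-constrained")
                continue
            if pred in group_of:
                gi = group_of[pred]
                if gi in seen_groups:
                    self.gamma_slots[seen_groups[gi]].append(j)
                    continue
                seen_groups[gi] = len(self.gamma_slots)
                self.gamma_slots.append([j])
                self.gamma_slot_names.append(f"gamma:={'|'.join(spec.equality_groups[gi])}")
            else:
                self.gamma_slots.append([j])
                self.gamma_slot_names.append(f"gamma:{pred}")

        self.names: list[str] = []
        if self.include_means:
            self.names += [f"nu:{t}" for t in spec.indicators]
        self.names += [f"lambda:{spec.indicators[k]}" for k in self.lam_free_idx]
        self.names += self.gamma_slot_names
        self.names += [f"theta:{spec.indicators[k]}" for k in self.theta_free_idx]
        if self.psi_fixed is None:
            self.names += ["psi"]
        self.n_free = len(self.names)

        # slices into the free vector
        i = 0
        self.sl_nu = slice(i, i + (self.q if self.include_means else 0))
        i = self.sl_nu.stop
        self.sl_lam = slice(i, i + len(self.lam_free_idx))
        i = self.sl_lam.stop
        self.sl_gam = slice(i, i + len(self.gamma_slots))
        i = self.sl_gam.stop
        self.sl_the = slice(i, i + len(self.theta_free_idx))
        i = self.sl_the.stop
        self.sl_psi = slice(i, i + (0 if self.psi_fixed is not None else 1))

    def unpack(self, u: np.ndarray, log_variances: bool = True):
        nu = np.zeros(self.q)
        if self.include_means:
            nu = u[self.sl_nu].copy()
        lam = np.where(np.isnan(self.lam_fixed), 0.0, self.lam_fixed)
        lam[self.lam_free_idx] = u[self.sl_lam]
        gam = np.where(np.isnan(self.gamma_fixed), 0.0, self.gamma_fixed)
        for slot, uval in zip(self.gamma_slots, u[self.sl_gam]):
            gam[slot] = uval
        the = np.where(np.isnan(self.theta_fixed), 0.0, self.theta_fixed)
        raw_the = u[self.sl_the]
        the[self.theta_free_idx] = np.exp(raw_the) if log_variances else raw_the
        if self.psi_fixed is not None:
            psi = self.psi_fixed
        else:
            psi = float(np.exp(u[self.sl_psi][0]) if log_variances else u[self.sl_psi][0])
        return nu, lam, gam, the, psi

    def pack(self, nu, lam, gam, the, psi, log_variances: bool = True) -> np.ndarray:
        u = np.empty(self.n_free)
        if self.include_means:
            u[self.sl_nu] = nu
        u[self.sl_lam] = np.asarray(lam)[self.lam_free_idx]
        u[self.sl_gam] = [np.asarray(gam)[slot[0]] for slot in self.gamma_slots]
        tv = np.asarray(the)[self.theta_free_idx]
        u[self.sl_the] = np.log(tv) if log_variances else tv
        if self.psi_fixed is None:
            u[self.sl_psi] = np.log(psi) if log_variances else psi
        return u

    def chain(self, g_nu, g_lam, g_gam, g_the, g_psi, the, psi, log_variances: bool = True):
        """Collect full-parameter gradients into the free vector."""
        g = np.empty(self.n_free)
        if self.include_means:
            g[self.sl_nu] = g_nu
        g[self.sl_lam] = g_lam[self.lam_free_idx]
        g[self.sl_gam] = [g_gam[slot].sum() for slot in self.gamma_slots]
        gt = g_the[self.theta_free_idx]
        g[self.sl_the] = gt * the[self.theta_free_idx] if log_variances else gt
        if self.psi_fixed is None:
            g[self.sl_psi] = g_psi * psi if log_variances else g_psi
        return g


# --------------------------------------------------------------------------
# sufficient statistics per missingness pattern
# --------------------------------------------------------------------------


@dataclass
class _PatternStats:
    obs: np.ndarray  # indicator indices observed in this pattern
    n: int
    sy: np.ndarray  # sum of observed y            (q_o,)
    Syy: np.ndarray  # sum of y y'                  (q_o, q_o)
    tx: np.ndarray  # sum of x                     (p,)
    Txx: np.ndarray  # sum of x x'                  (p, p)
    Tyx: np.ndarray  # sum of y x'                  (q_o, p)


def _pattern_stats(Y: np.ndarray, X: np.ndarray) -> list[_PatternStats]:
    """Group rows by indicator-missingness pattern and accumulate moments."""
    n, q = Y.shape
    obs_mask = ~np.isnan(Y)
    codes = obs_mask @ (1 << np.arange(q))
    stats = []
    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        obs = np.flatnonzero(obs_mask[rows[0]])
        if obs.size == 0:
            continue  # nothing observed on the conditional side
        Yo = Y[np.ix_(rows, obs)]
        Xr = X[rows]
        stats.append(
            _PatternStats(
                obs=obs,
                n=len(rows),
                sy=Yo.sum(axis=0),
                Syy=Yo.T @ Yo,
                tx=Xr.sum(axis=0),
                Txx=Xr.T @ Xr,
                Tyx=Yo.T @ Xr,
            )
        )
    return stats


def _stats_from_moments(S: np.ndarray, q: int, n: int) -> list[_PatternStats]:
    """Single complete-data 'pattern' built from centered moments n*S."""
    T = n * S
    return [
        _PatternStats(
            obs=np.arange(q),
            n=n,
            sy=np.zeros(q),
            Syy=T[:q, :q],
            tx=np.zeros(S.shape[0] - q),
            Txx=T[q:, q:],
            Tyx=T[:q, q:],
        )
    ]


# --------------------------------------------------------------------------
# conditional negative log-likelihood with analytic gradient
# --------------------------------------------------------------------------


def _cond_nll_grad(u, pm: _ParamMap, stats: list[_PatternStats], want_grad=True, log_variances=True):
    nu, lam, gam, the, psi = pm.unpack(u, log_variances)
    nll = 0.0
    g_nu = np.zeros(pm.q)
    g_lam = np.zeros(pm.q)
    g_gam = np.zeros(pm.p)
    g_the = np.zeros(pm.q)
    g_psi = 0.0

    for st in stats:
        o = st.obs
        lo = lam[o]
        no = nu[o]
        V = psi * np.outer(lo, lo) + np.diag(the[o])
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return (np.inf, np.zeros(pm.n_free)) if want_grad else np.inf
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        W = np.linalg.inv(V)

        if pm.p:
            m = st.Tyx @ gam  # sum_i y_i * c_i
            s1 = float(st.tx @ gam)  # sum_i c_i
            s2 = float(gam @ st.Txx @ gam)  # sum_i c_i^2
        else:
            m = np.zeros(len(o))
            s1 = 0.0
            s2 = 0.0

        # C = sum_i r_i r_i'  with  r_i = y_i - nu_o - lam_o c_i
        C = (
            st.Syy
            - np.outer(st.sy, no)
            - np.outer(no, st.sy)
            - np.outer(m, lo)
            - np.outer(lo, m)
            + st.n * np.outer(no, no)
            + s1 * (np.outer(no, lo) + np.outer(lo, no))
            + s2 * np.outer(lo, lo)
        )
        nll += 0.5 * (st.n * (len(o) * _LOG2PI + logdet) + float(np.sum(W * C)))
        if not want_grad:
            continue

        A = 0.5 * st.n * W - 0.5 * (W @ C @ W)  # d nll / d V (symmetric)
        Wl = W @ lo
        # mean-part pieces
        if pm.include_means:
            g_nu[o] += W @ (-st.sy + st.n * no + s1 * lo)
        g_lam[o] += W @ (-m + s1 * no + s2 * lo)  # mean part
        g_lam[o] += 2.0 * psi * (A @ lo)  # covariance part
        if pm.p:
            g_gam += -(st.Tyx.T @ Wl) + float(no @ Wl) * st.tx + float(lo @ Wl) * (st.Txx @ gam)
        g_the[o] += np.diag(A)
        g_psi += float(lo @ A @ lo)

    if not want_grad:
        return nll
    grad = pm.chain(g_nu, g_lam, g_gam, g_the, g_psi, the, psi, log_variances)
    return nll, grad


# --------------------------------------------------------------------------
# estimates container
# --------------------------------------------------------------------------


@dataclass
class ParameterEstimates:
    """Converged estimates with raw and standardized solutions."""

    raw: dict
    standardized: dict
    loglik: float
    n_obs: int
    converged: bool
    n_free: int
    spec: MimicModelSpec
    method: str
    # structural arrays for downstream computation
    nu: np.ndarray = None
    lam: np.ndarray = None
    gamma: np.ndarray = None
    theta: np.ndarray = None
    psi: float = None
    predictor_cov: np.ndarray = None
    predictor_means: np.ndarray = None
    loglik_conditional: float = None
    loglik_saturated: float = None
    f_min: float = None
    grad_norm: float = None
    n_iter: int = 0
    se: dict | None = None
    vcov: dict | None = None

    @property
    def factor_variance(self) -> float:
        """Model-implied variance of the latent factor."""
        explained = 0.0
        if len(self.gamma):
            explained = float(self.gamma @ self.predictor_cov @ self.gamma)
        return explained + self.psi

    def to_frame(self) -> pd.DataFrame:
        """Tidy (parameter, raw, standardized, se) table."""
        rows = []
        for name, val in self.raw.items():
            rows.append(
                {
                    "parameter": name,
                    "raw": val,
                    "standardized": self.standardized.get(name, np.nan),
                    "se": (self.se or {}).get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# moments, discrepancy, implied structure
# --------------------------------------------------------------------------


@dataclass
class MomentSummary:
    """Sample covariance and means of the modeled variables."""

    S: np.ndarray
    means: np.ndarray
    n_obs: int
    names: list[str] = None

    @property
    def p(self) -> int:
        return self.S.shape[0]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("S must be symmetric")
        self.S = S
        self.means = np.asarray(self.means, dtype=float)


def sample_moments(data: pd.DataFrame, names: Sequence[str]) -> MomentSummary:
    """Listwise-complete ML (ddof=0) moments of the named columns."""
    sub = data[list(names)].dropna()
    X = sub.to_numpy(dtype=float)
    n = X.shape[0]
    mu = X.mean(axis=0)
    Xc = X - mu
    return MomentSummary(S=(Xc.T @ Xc) / n, means=mu, n_obs=n, names=list(names))


def ml_discrepancy(S, sigma) -> float:
    """Maximum-likelihood fitting function F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Nonnegative, zero iff the implied covariance equals the sample one.
    """
    Smat = S.S if isinstance(S, MomentSummary) else np.asarray(S, dtype=float)
    Sig = np.asarray(sigma, dtype=float)
    if Smat.shape != Sig.shape:
        raise ValueError("S and Sigma must have the same dimension")
    p = Smat.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(Smat)
    sign_m, logdet_m = np.linalg.slogdet(Sig)
    if sign_m <= 0:
        raise np.linalg.LinAlgError(
            f"implied covariance is singular or indefinite (condition number "
            f"{np.linalg.cond(Sig):.3e})"
        )
    if sign_s <= 0:
        raise np.linalg.LinAlgError("sample covariance is singular or indefinite")
    F = logdet_m + float(np.trace(np.linalg.solve(Sig, Smat))) - logdet_s - p
    return max(F, 0.0)


def implied_moments(
    spec: MimicModelSpec,
    params: Mapping[str, float],
    predictor_cov: np.ndarray | None = None,
    predictor_means: np.ndarray | None = None,
):
    """Model-implied covariance and mean vector over indicators then predictors.

    The predictor block is saturated: it is taken from ``predictor_cov`` /
    ``predictor_means`` (or ``phi:<a>,<b>`` / ``mu:<x>`` entries of
    ``params``), defaulting to unit variances, zero covariances and zero
    means.
    """
    q = len(spec.indicators)
    p = len(spec.predictors)
    missing = []
    lam = np.empty(q)
    the = np.empty(q)
    nu = np.zeros(q)
    for k, task in enumerate(spec.indicators):
        fixed = spec.loading_fixed_value(task)
        key = f"lambda:{task}"
        if key in params:
            lam[k] = params[key]
        elif fixed is not None:
            lam[k] = fixed
        else:
            missing.append(key)
            lam[k] = np.nan
        tkey = f"theta:{task}"
        if tkey in params:
            the[k] = params[tkey]
        elif tkey in spec.fixed:
            the[k] = spec.fixed[tkey]
        else:
            missing.append(tkey)
        nu[k] = params.get(f"nu:{task}", 0.0)
    gam = np.empty(p)
    for j, pred in enumerate(spec.predictors):
        key = f"gamma:{pred}"
        if key in params:
            gam[j] = params[key]
        elif key in spec.fixed:
            gam[j] = spec.fixed[key]
        else:
            missing.append(key)
    if "psi" in params:
        psi = float(params["psi"])
    elif "psi" in spec.fixed:
        psi = float(spec.fixed["psi"])
    else:
        missing.append("psi")
    if missing:
        raise ValueError(f"parameter map incomplete for this model: missing {missing}")

    if predictor_cov is None:
        phi = np.eye(p)
        for j, a in enumerate(spec.predictors):
            for k, b in enumerate(spec.predictors):
                key = f"phi:{a},{b}"
                if key in params:
                    phi[j, k] = phi[k, j] = params[key]
    else:
        phi = np.asarray(predictor_cov, dtype=float)
    if predictor_means is None:
        mux = np.zeros(p)
        for j, a in enumerate(spec.predictors):
            mux[j] = params.get(f"mu:{a}", 0.0)
    else:
        mux = np.asarray(predictor_means, dtype=float)

    fvar = float(gam @ phi @ gam) + psi if p else psi
    cov_x_eta = phi @ gam if p else np.zeros(0)
    Sigma = np.empty((q + p, q + p))
    Sigma[:q, :q] = fvar * np.outer(lam, lam) + np.diag(the)
    Sigma[:q, q:] = np.outer(lam, cov_x_eta)
    Sigma[q:, :q] = Sigma[:q, q:].T
    Sigma[q:, q:] = phi
    mu = np.concatenate([nu + lam * float(gam @ mux if p else 0.0), mux])
    return Sigma, mu


def fiml_loglik(
    data: pd.DataFrame,
    spec: MimicModelSpec,
    params: Mapping[str, float],
    predictor_cov: np.ndarray | None = None,
    predictor_means: np.ndarray | None = None,
) -> float:
    """Casewise Gaussian log-likelihood over each row's observed variables.

    Rows in which every modeled variable is missing are excluded with a
    warning reporting the count; with complete data this reduces to the
    ordinary joint-normal log-likelihood.
    """
    names = list(spec.indicators) + list(spec.predictors)
    Sigma, mu = implied_moments(spec, params, predictor_cov, predictor_means)
    Z = data[names].to_numpy(dtype=float)
    obs = ~np.isnan(Z)
    empty = ~obs.any(axis=1)
    if empty.any():
        warnings.warn(f"excluded {int(empty.sum())} row(s) with all modeled variables missing")
        Z, obs = Z[~empty], obs[~empty]
    total = 0.0
    codes = obs @ (1 << np.arange(obs.shape[1]))
    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        o = np.flatnonzero(obs[rows[0]])
        So = Sigma[np.ix_(o, o)]
        L = np.linalg.cholesky(So)
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        R = Z[np.ix_(rows, o)] - mu[o]
        sol = np.linalg.solve(L, R.T)
        quad = float(np.sum(sol**2))
        total += -0.5 * (len(rows) * (len(o) * _LOG2PI + logdet) + quad)
    return total


# --------------------------------------------------------------------------
# saturated models (closed form / EM)
# --------------------------------------------------------------------------


def em_saturated_moments(
    data: pd.DataFrame, names: Sequence[str], max_iter: int = 500, tol: float = 1e-8
):
    """EM estimate of the saturated mean/covariance under MAR missingness.

    Returns ``(mu, S, loglik, n)`` where ``loglik`` is the observed-data
    log-likelihood at convergence and ``S`` uses the ML (1/n) convention.
    Rows missing every variable are dropped.
    """
    Z = data[list(names)].to_numpy(dtype=float)
    obs = ~np.isnan(Z)
    Z = Z[obs.any(axis=1)]
    obs = ~np.isnan(Z)
    n, d = Z.shape
    # start from available-case moments
    mu = np.nanmean(Z, axis=0)
    Zc = np.where(obs, Z - mu, 0.0)
    denom = obs.T.astype(float) @ obs.astype(float)
    S = (Zc.T @ Zc) / np.maximum(denom, 1.0)
    S[np.diag_indices_from(S)] += 1e-6
    # make sure the start is PD
    w, V = np.linalg.eigh(S)
    S = (V * np.maximum(w, 1e-8)) @ V.T

    codes = obs @ (1 << np.arange(d))
    patterns = [(np.flatnonzero(codes == c), np.flatnonzero(obs[np.flatnonzero(codes == c)[0]])) for c in np.unique(codes)]

    prev_ll = -np.inf
    ll = prev_ll
    for _ in range(max_iter):
        T1 = np.zeros(d)
        T2 = np.zeros((d, d))
        ll = 0.0
        for rows, o in patterns:
            m = np.setdiff1d(np.arange(d), o, assume_unique=True)
            Soo = S[np.ix_(o, o)]
            L = np.linalg.cholesky(Soo)
            Ro = Z[np.ix_(rows, o)] - mu[o]
            sol = np.linalg.solve(L, Ro.T)
            ll += -0.5 * (
                len(rows) * (len(o) * _LOG2PI + 2.0 * float(np.log(np.diag(L)).sum()))
                + float(np.sum(sol**2))
            )
            Zfill = np.empty((len(rows), d))
            Zfill[:, o] = Z[np.ix_(rows, o)]
            if m.size:
                B = np.linalg.solve(Soo, S[np.ix_(o, m)])  # regression of missing on observed
                Zfill[:, m] = mu[m] + Ro @ B
                Cmm = S[np.ix_(m, m)] - S[np.ix_(m, o)] @ B  # conditional covariance
            T1 += Zfill.sum(axis=0)
            T2 += Zfill.T @ Zfill
            if m.size:
                T2[np.ix_(m, m)] += len(rows) * Cmm
        mu = T1 / n
        S = T2 / n - np.outer(mu, mu)
        if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            break
        prev_ll = ll
    return mu, S, ll, n


def saturated_loglik(data: pd.DataFrame, spec: MimicModelSpec, method: str = "fiml") -> float:
    """Log-likelihood of the saturated (unrestricted Gaussian) model.

    For complete data this is closed-form; with missing indicator entries it
    is estimated by EM, matching the FIML convention for chi-square
    statistics.
    """
    names = list(spec.indicators) + list(spec.predictors)
    Z = data[names]
    if method == "ml_complete" or not Z.isna().to_numpy().any():
        mom = sample_moments(data, names)
        _, logdet = np.linalg.slogdet(mom.S)
        return -0.5 * mom.n_obs * (mom.p * _LOG2PI + logdet + mom.p)
    _, _, ll, _ = em_saturated_moments(data, names)
    return ll


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _start_values(pm: _ParamMap, Syy: np.ndarray, ybar: np.ndarray):
    """Deterministic starts: loadings from the first principal component of
    the indicator covariance (scaled so the reference loading is 1), paths
    zero, variances at half the sample values."""
    q = pm.q
    w, V = np.linalg.eigh(Syy)
    v = V[:, -1]
    ref = pm.spec.indicators.index(pm.spec.reference_indicator)
    if abs(v[ref]) < 1e-8:
        v = np.ones(q)
    lam0 = v / v[ref]
    lam0 = np.where(np.isnan(pm.lam_fixed), lam0, pm.lam_fixed)
    psi0 = max(float(w[-1]) * v[ref] ** 2 * 0.5, 0.05 * float(np.diag(Syy).mean()))
    the0 = np.maximum(0.5 * np.diag(Syy), 1e-3)
    the0 = np.where(np.isnan(pm.theta_fixed), the0, np.maximum(pm.theta_fixed, 1e-12))
    gam0 = np.where(np.isnan(pm.gamma_fixed), 0.0, pm.gamma_fixed)
    return pm.pack(ybar, lam0, gam0, the0, psi0)


def _x_block_loglik(Sxx: np.ndarray, n: int) -> float:
    if Sxx.size == 0:
        return 0.0
    p = Sxx.shape[0]
    _, logdet = np.linalg.slogdet(Sxx)
    return -0.5 * n * (p * _LOG2PI + logdet + p)


def fit_model(
    data: pd.DataFrame,
    spec: MimicModelSpec,
    method: str = "fiml",
    max_iter: int = 5000,
    gtol: float = 1e-6,
    compute_saturated: bool = True,
) -> ParameterEstimates:
    """Estimate a CFA/MIMIC model by ML (listwise complete) or FIML.

    ``method='ml_complete'`` drops rows with any missing modeled variable
    and minimizes the ML discrepancy of the sample covariance; ``'fiml'``
    maximizes the casewise likelihood over each row's observed indicators
    (predictors must be complete).  Equality constraints are enforced
    exactly through parameter tying.
    """
    if method not in {"ml_complete", "fiml"}:
        raise ValueError(f"unknown method {method!r}")
    names = list(spec.indicators) + list(spec.predictors)
    frame = data[names]
    if spec.predictors and frame[spec.predictors].isna().to_numpy().any():
        raise ValueError("predictors contain missing values; only indicator missingness is supported")

    q, p = len(spec.indicators), len(spec.predictors)

    if method == "ml_complete" or not frame.isna().to_numpy().any():
        sub = frame.dropna()
        n = len(sub)
        mom = sample_moments(sub, names)
        pm = _ParamMap(spec, include_means=False)
        stats = _stats_from_moments(mom.S, q, n)
        Sxx = mom.S[q:, q:]
        mu_x = mom.means[q:]
        ybar = mom.means[:q]
        Syy = mom.S[:q, :q]
    else:
        sub = frame[frame[spec.indicators].notna().any(axis=1)]
        dropped = len(frame) - len(sub)
        if dropped:
            warnings.warn(f"excluded {dropped} row(s) with all indicators missing")
        n = len(sub)
        Y = sub[spec.indicators].to_numpy(dtype=float)
        X = sub[spec.predictors].to_numpy(dtype=float) if p else np.zeros((n, 0))
        pm = _ParamMap(spec, include_means=True)
        stats = _pattern_stats(Y, X)
        mu_x = X.mean(axis=0) if p else np.zeros(0)
        Xc = X - mu_x
        Sxx = (Xc.T @ Xc) / n if p else np.zeros((0, 0))
        ybar = np.nanmean(Y, axis=0)
        Yc = np.where(np.isnan(Y), 0.0, Y - ybar)
        cnt = (~np.isnan(Y)).T.astype(float) @ (~np.isnan(Y)).astype(float)
        Syy = (Yc.T @ Yc) / np.maximum(cnt, 1.0)

    if n <= pm.n_free:
        raise ValueError(f"n_obs={n} is not larger than the free parameter count {pm.n_free}")

    u0 = _start_values(pm, Syy, ybar)
    nll0 = _cond_nll_grad(u0, pm, stats, want_grad=False)

    res = optimize.minimize(
        _cond_nll_grad,
        u0,
        args=(pm, stats),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12, "maxcor": 20},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-4)
    if not converged:
        warnings.warn(
            f"optimizer did not converge: best NLL {res.fun:.6g} (start {nll0:.6g}), "
            f"max|grad| {grad_norm:.3e} after {res.nit} iterations"
        )
    nu, lam, gam, the, psi = pm.unpack(res.x)
    cond_ll = -float(res.fun)
    ll = cond_ll + _x_block_loglik(Sxx, n)

    raw = {}
    for k, task in enumerate(spec.indicators):
        raw[f"lambda:{task}"] = float(lam[k])
        raw[f"theta:{task}"] = float(the[k])
        if pm.include_means:
            raw[f"nu:{task}"] = float(nu[k])
    for j, pred in enumerate(spec.predictors):
        raw[f"gamma:{pred}"] = float(gam[j])
    raw["psi"] = float(psi)

    # free parameters of the full model: conditional block plus the
    # saturated predictor moments (and their means under a meanstructure)
    n_free = pm.n_free + p * (p + 1) // 2 + (p if pm.include_means else 0)

    est = ParameterEstimates(
        raw=raw,
        standardized={},
        loglik=ll,
        n_obs=n,
        converged=converged,
        n_free=n_free,
        spec=spec,
        method=method,
        nu=nu,
        lam=lam,
        gamma=gam,
        theta=the,
        psi=float(psi),
        predictor_cov=Sxx,
        predictor_means=mu_x,
        loglik_conditional=cond_ll,
        grad_norm=grad_norm,
        n_iter=int(res.nit),
    )
    est.standardized = _standardized_map(est)
    if compute_saturated:
        est.loglik_saturated = saturated_loglik(sub, spec, method)
        est.f_min = max(2.0 * (est.loglik_saturated - ll) / n, 0.0)
    return est


def _standardized_map(est: ParameterEstimates) -> dict:
    spec = est.spec
    fvar = est.factor_variance
    if fvar <= 0:
        raise ValueError("implied factor variance is not positive; cannot standardize")
    sd_eta = np.sqrt(fvar)
    sd_y = np.sqrt(fvar * est.lam**2 + est.theta)
    std = {}
    for k, task in enumerate(spec.indicators):
        if sd_y[k] <= 0:
            raise ValueError(f"implied variance of {task} is zero; cannot standardize")
        std[f"lambda:{task}"] = float(est.lam[k] * sd_eta / sd_y[k])
        std[f"theta:{task}"] = float(est.theta[k] / sd_y[k] ** 2)
    if len(spec.predictors):
        sd_x = np.sqrt(np.diag(est.predictor_cov))
        for j, pred in enumerate(spec.predictors):
            std[f"gamma:{pred}"] = float(est.gamma[j] * sd_x[j] / sd_eta)
    std["psi"] = float(est.psi / fvar)
    return std


def standardize(est: ParameterEstimates, spec: MimicModelSpec | None = None) -> ParameterEstimates:
    """All-variables-standardized solution (loadings and paths rescaled by
    model-implied standard deviations).  Idempotent on an already
    standardized solution."""
    spec = spec or est.spec
    std = _standardized_map(est)
    out = ParameterEstimates(**{**est.__dict__, "standardized": std})
    return out


# --------------------------------------------------------------------------
# robust (sandwich) standard errors
# --------------------------------------------------------------------------


def _casewise_scores(est: ParameterEstimates, Y: np.ndarray, X: np.ndarray, pm: _ParamMap):
    """Per-row gradient of the conditional log-likelihood, raw scale."""
    n = Y.shape[0]
    scores = np.zeros((n, pm.n_free))
    nu, lam, gam, the, psi = est.nu, est.lam, est.gamma, est.theta, est.psi
    obs_mask = ~np.isnan(Y)
    codes = obs_mask @ (1 << np.arange(Y.shape[1]))
    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        o = np.flatnonzero(obs_mask[rows[0]])
        if o.size == 0:
            continue
        lo, no = lam[o], nu[o]
        V = psi * np.outer(lo, lo) + np.diag(the[o])
        W = np.linalg.inv(V)
        Xr = X[rows] if pm.p else np.zeros((len(rows), 0))
        c = Xr @ gam if pm.p else np.zeros(len(rows))
        R = Y[np.ix_(rows, o)] - no - np.outer(c, lo)
        RW = R @ W  # rows of W r_i
        lWr = RW @ lo  # lambda' W r_i per row
        Wl = W @ lo
        g_nu = np.zeros((len(rows), pm.q))
        g_nu[:, o] = RW
        g_lam = np.zeros((len(rows), pm.q))
        g_lam[:, o] = c[:, None] * RW + psi * (RW * lWr[:, None] - Wl)
        g_gam = Xr * (lWr[:, None]) if pm.p else np.zeros((len(rows), 0))
        g_the = np.zeros((len(rows), pm.q))
        g_the[:, o] = 0.5 * (RW**2 - np.diag(W))
        g_psi = 0.5 * (lWr**2 - float(lo @ Wl))
        # assemble into free-vector layout (raw-scale variances)
        block = []
        if pm.include_means:
            block.append(g_nu)
        block.append(g_lam[:, pm.lam_free_idx])
        block.append(np.column_stack([g_gam[:, slot].sum(axis=1) for slot in pm.gamma_slots]) if pm.gamma_slots else np.zeros((len(rows), 0)))
        block.append(g_the[:, pm.theta_free_idx])
        if pm.psi_fixed is None:
            block.append(g_psi[:, None])
        scores[rows] = np.column_stack(block)
    return scores


def sandwich_se(data: pd.DataFrame, spec: MimicModelSpec, est: ParameterEstimates) -> dict:
    """Huber-White robust standard errors A^-1 B A^-1.

    A is the observed information (numerical derivative of the analytic
    score), B the outer product of casewise scores.  Also attaches
    information-based SEs and both parameter covariance matrices to
    ``est.vcov``.  Singular information falls back to a pseudo-inverse with
    a warning.
    """
    if not est.converged:
        raise ValueError("estimates did not converge; standard errors are meaningless")
    pm = _ParamMap(spec, include_means=est.method != "ml_complete" and spec.meanstructure)
    names = list(spec.indicators) + list(spec.predictors)
    frame = data[names]
    if est.method == "ml_complete":
        frame = frame.dropna()
    else:
        frame = frame[frame[spec.indicators].notna().any(axis=1)]
    Y = frame[spec.indicators].to_numpy(dtype=float)
    X = frame[spec.predictors].to_numpy(dtype=float) if pm.p else np.zeros((len(frame), 0))
    if est.method == "ml_complete":
        # centered formulation: scores computed on centered data without nu
        Y = Y - Y.mean(axis=0)
        X = X - X.mean(axis=0) if pm.p else X

    stats = _pattern_stats(Y, X)
    u_hat = pm.pack(est.nu, est.lam, est.gamma, est.theta, est.psi, log_variances=False)

    def grad_raw(u):
        _, g = _cond_nll_grad(u, pm, stats, want_grad=True, log_variances=False)
        return g

    k = pm.n_free
    A = np.zeros((k, k))
    h = 1e-5 * np.maximum(np.abs(u_hat), 1.0)
    for i in range(k):
        up, dn = u_hat.copy(), u_hat.copy()
        up[i] += h[i]
        dn[i] -= h[i]
        A[:, i] = (grad_raw(up) - grad_raw(dn)) / (2 * h[i])
    A = 0.5 * (A + A.T)

    scores = _casewise_scores(est, Y, X, pm)
    B = scores.T @ scores

    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        warnings.warn("observed information is singular; using pseudo-inverse")
        Ainv = np.linalg.pinv(A)
    vcov_sand = Ainv @ B @ Ainv
    vcov_info = Ainv
    se_sand = np.sqrt(np.maximum(np.diag(vcov_sand), 0.0))
    se_info = np.sqrt(np.maximum(np.diag(vcov_info), 0.0))
    se = dict(zip(pm.names, se_sand))
    est.se = se
    est.vcov = {
        "param_names": list(pm.names),
        "sandwich": vcov_sand,
        "information": vcov_info,
        "se_information": dict(zip(pm.names, se_info)),
    }
    return se
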