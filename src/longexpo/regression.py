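"""Shared estimation machinery.

Four engines used throughout the method modules:

* :func:`fit_logistic` — logistic MLE by iteratively reweighted least squares;
* :func:`fit_map_logistic` — MAP logistic with a temporally correlated
  (AR(1)) Gaussian shrinkage prior on the block of visit-specific exposure
  coefficients, the ridge-like adaptation used to stabilize correlated
  repeated-exposure coefficients;
* :func:`fit_lmm` — REML linear mixed model of the ln exposure on time with
  random intercept (and optionally random slope), returning per-subject BLUPs;
* :func:`fit_pooled_gee` — working-independence GEE with visit-specific
  coefficients, a subject-clustered sandwich covariance and a Wald test of
  equal exposure effects across visits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

from .cohort import Cohort
from .design import build_design

__all__ = ["GlmFit", "LmmFit", "GeeFit", "fit_logistic", "fit_map_logistic",
           "fit_lmm", "fit_pooled_gee"]

Z_95 = stats.norm.ppf(0.975)


class FitError(RuntimeError):
    pass


@dataclass
class GlmFit:
    """A fitted (possibly penalized) logistic model."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik: float
    n_used: int
    converged: bool
    iterations: int
    notes: list = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.coefficients.index)

    def summary(self) -> pd.DataFrame:
        """Coefficient table with OR, Wald 95% CI and p-values."""
        beta = self.coefficients
        se = self.se
        z = beta / se
        return pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "or": np.exp(beta),
                "ci_low": np.exp(beta - Z_95 * se),
                "ci_high": np.exp(beta + Z_95 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def wald_p(self, name: str) -> float:
        z = self.coefficients[name] / self.se[name]
        return float(2 * stats.norm.sf(abs(z)))


@dataclass
class LmmFit:
    """REML fit of the exposure trajectory mixed model."""

    fixed_effects: pd.Series
    var_intercept: float
    var_slope: float
    re_correlation: float
    resid_var: float
    blups: pd.DataFrame          # index subject_id; columns intercept[, slope]
    used_slope: bool
    reml_loglik: float
    time_center_days: float
    notes: list = field(default_factory=list)


@dataclass
class GeeFit:
    """Pooled working-independence GEE with visit-specific coefficients."""

    visit_betas: pd.Series       # exposure coefficient per visit
    visit_se: pd.Series          # sandwich SE per visit exposure coefficient
    params: pd.Series            # full coefficient vector
    sandwich_cov: pd.DataFrame
    n_clusters: int
    equality_stat: float
    equality_df: int
    equality_p: float
    notes: list = field(default_factory=list)


# --------------------------------------------------------------------- #
# Logistic MLE
# --------------------------------------------------------------------- #

def _as_matrix(design) -> tuple[np.ndarray, list]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.asarray(design, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _logistic_loglik(y, eta):
    # numerically safe Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(y, design, offset=None, tol: float = 1e-8, max_iter: int = 100,
                 separation_threshold: float = 10.0) -> GlmFit:
    """Logistic MLE by IRLS.

    Convergence when the deviance change drops below ``tol``.  Suspected
    separation (a standardized coefficient exceeding ``separation_threshold``
    while the deviance keeps falling) is flagged and returned with
    ``converged=False`` rather than raised.
    """
    X, names = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    if not np.isin(np.unique(y), [0.0, 1.0]).all():
        raise FitError("response must be binary 0/1")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise FitError("design matrix is rank deficient")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p)
    dev_old = np.inf
    converged = False
    notes: list = []
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta + off
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta - off + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X
        beta_new = np.linalg.solve(H, XtW @ z)
        dev = -2.0 * _logistic_loglik(y, X @ beta_new + off)
        if not np.isfinite(dev):
            notes.append("divergent deviance")
            break
        step_ratio = dev_old - dev
        beta = beta_new
        if abs(step_ratio) < tol:
            converged = True
            dev_old = dev
            break
        dev_old = dev

    eta = X @ beta + off
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (X.T * w) @ X
    cov = np.linalg.inv(H)
    scale = np.std(X, axis=0)
    scale[scale == 0] = 1.0
    if np.any(np.abs(beta * scale) > separation_threshold):
        converged = False
        notes.append("possible separation: a standardized coefficient exceeds threshold")
        warnings.warn("possible separation detected in logistic fit")
    return GlmFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        loglik=_logistic_loglik(y, eta),
        n_used=n,
        converged=converged,
        iterations=it,
        notes=notes,
    )


# --------------------------------------------------------------------- #
# MAP logistic with AR(1) Gaussian prior on the exposure block
# --------------------------------------------------------------------- #

def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _fit_penalized(y, X, P_full, tol=1e-10, max_iter=200):
    """Newton solve of the penalized logistic log-likelihood."""
    n, p = X.shape
    beta = np.zeros(p)
    obj_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - P_full @ beta
        H = (X.T * w) @ X + P_full
        step = np.linalg.solve(H, grad)
        # halving for safety
        for _ in range(30):
            cand = beta + step
            obj = _logistic_loglik(y, X @ cand) - 0.5 * cand @ P_full @ cand
            if obj >= obj_old - 1e-12:
                break
            step *= 0.5
        beta = cand
        if abs(obj - obj_old) < tol:
            return beta, H, obj, it, True
        obj_old = obj
    return beta, H, obj, max_iter, False


def fit_map_logistic(y, design, exposure_block, tau2=None, rho=None,
                     tau2_grid=(0.01, 0.1, 1.0, 10.0),
                     rho_grid=(0.0, 0.3, 0.6, 0.9)) -> GlmFit:
    """MAP logistic regression with an AR(1) Gaussian prior.

    The coefficients named in ``exposure_block`` (visit-ordered) receive a
    mean-zero Gaussian prior with covariance ``tau2 * R(rho)`` where ``R`` is
    AR(1) over visit order; intercept and covariates are unpenalized.  When
    ``tau2``/``rho`` are omitted they are chosen on a small grid by the
    Laplace-approximate marginal likelihood.
    """
    X, names = _as_matrix(design)
    y = np.asarray(y, dtype=float)
    block = [names.index(b) for b in exposure_block]
    nb = len(block)

    def penalty(t2, r):
        if t2 <= 0:
            raise FitError("tau2 must be positive")
        if not (-1 < r < 1):
            raise FitError("rho must lie strictly inside (-1, 1)")
        R = _ar1_corr(nb, r)
        Pb = np.linalg.inv(t2 * R)
        P = np.zeros((X.shape[1], X.shape[1]))
        for a, ia in enumerate(block):
            for b, ib in enumerate(block):
                P[ia, ib] = Pb[a, b]
        return P, float(np.linalg.slogdet(t2 * R)[1])

    def fit_one(t2, r):
        P, logdet_prior = penalty(t2, r)
        beta, H, obj, it, conv = _fit_penalized(y, X, P)
        # Laplace approximate log marginal likelihood (constants dropped)
        sign, logdet_H = np.linalg.slogdet(H)
        lml = obj - 0.5 * logdet_prior - 0.5 * logdet_H
        return beta, H, obj, it, conv, lml

    if tau2 is not None and rho is not None:
        beta, H, obj, it, conv, _ = fit_one(float(tau2), float(rho))
        chosen = (float(tau2), float(rho))
    else:
        best = None
        for t2 in tau2_grid:
            for r in rho_grid:
                out = fit_one(t2, r)
                if best is None or out[5] > best[0][5]:
                    best = (out, (t2, r))
        (beta, H, obj, it, conv, _), chosen = best
    cov = np.linalg.inv(H)  # Laplace posterior covariance
    eta = X @ beta
    return GlmFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        loglik=_logistic_loglik(y, eta),
        n_used=len(y),
        converged=conv,
        iterations=it,
        notes=[f"map prior tau2={chosen[0]}, rho={chosen[1]}"],
    )


# --------------------------------------------------------------------- #
# Linear mixed model with BLUPs (batched REML)
# --------------------------------------------------------------------- #

def _theta_to_gamma(theta: np.ndarray, q: int) -> np.ndarray:
    """Log-Cholesky parameters -> scaled random-effect covariance G/sigma2.

    Entries are clipped to +-9 (variance ratios capped near e^18): beyond
    that the GLS fixed effects are numerically unidentified, and the cap
    keeps the near-noiseless limit stable without affecting realistic fits.
    """
    theta = np.clip(theta, -9.0, 9.0)
    L = np.zeros((q, q))
    if q == 1:
        L[0, 0] = np.exp(theta[0])
    else:
        L[0, 0] = np.exp(theta[0])
        L[1, 0] = theta[1]
        L[1, 1] = np.exp(theta[2])
    return L @ L.T


def fit_lmm(cohort: Cohort, random_slope: bool = True, fixed_covariates=None,
            n_restarts: int = 5, seed: int = 0) -> LmmFit:
    """REML mixed model of ln exposure on time.

    Fixed effects: intercept, time (weeks, centered at the cohort mean) and
    any ``fixed_covariates`` (time-varying covariates enter here).  Random:
    intercept, plus slope when ``random_slope``.  BLUPs by the standard
    conditional mean given the REML variance components.
    """
    if cohort.exposure_scale != "ln":
        raise FitError("fit_lmm expects an ln-scale cohort")
    if fixed_covariates is None:
        fixed_covariates = list(cohort.model_tv_covariates())
    d = cohort.data.sort_values(["subject_id", "visit"])
    counts = d.groupby("subject_id", sort=False).size()
    if random_slope and (counts >= 2).sum() < 2:
        raise FitError("random slope needs >=2 subjects with >=2 visits")

    t_center = float(d["time_days"].mean())
    t_weeks = (d["time_days"].to_numpy(dtype=float) - t_center) / 7.0
    Xcov = build_design(d, fixed_covariates, intercept=False)
    F = np.column_stack([np.ones(len(d)), t_weeks, Xcov.to_numpy(dtype=float)])
    fixed_names = ["intercept", "time_weeks", *Xcov.columns]
    x = d["exposure"].to_numpy(dtype=float)
    q = 2 if random_slope else 1
    Z = np.column_stack([np.ones(len(d)), t_weeks])[:, :q]

    # Per-subject sufficient statistics: with V_i = I + Z_i G Z_i', Woodbury
    # reduces every REML quantity to q x q algebra, so one criterion
    # evaluation is a handful of batched (N, q, q) operations.
    sid = d["subject_id"].to_numpy()
    _, starts = np.unique(sid, return_index=True)
    starts = np.sort(starts)
    ends = np.append(starts[1:], len(d))
    subj_order = sid[starts]
    M, p = F.shape
    nsub = len(starts)
    C = np.zeros((nsub, q, q))     # Z_i' Z_i
    D = np.zeros((nsub, q, p))     # Z_i' F_i
    e = np.zeros((nsub, q))        # Z_i' x_i
    for i, (a, bnd) in enumerate(zip(starts, ends)):
        Zi, Fi, xi = Z[a:bnd], F[a:bnd], x[a:bnd]
        C[i] = Zi.T @ Zi
        D[i] = Zi.T @ Fi
        e[i] = Zi.T @ xi
    FtF = F.T @ F
    Ftx = F.T @ x
    xtx = float(x @ x)
    Iq = np.eye(q)

    def _batch_inv(Mb):
        if q == 1:
            return 1.0 / Mb
        det = Mb[:, 0, 0] * Mb[:, 1, 1] - Mb[:, 0, 1] * Mb[:, 1, 0]
        inv = np.empty_like(Mb)
        inv[:, 0, 0] = Mb[:, 1, 1]
        inv[:, 1, 1] = Mb[:, 0, 0]
        inv[:, 0, 1] = -Mb[:, 0, 1]
        inv[:, 1, 0] = -Mb[:, 1, 0]
        return inv / det[:, None, None], det

    def _core(G):
        ICG = Iq[None] + C @ G                    # (N, q, q)
        if q == 1:
            det = ICG[:, 0, 0]
            T = (G[None] @ (1.0 / det)[:, None, None])
        else:
            inv, det = _batch_inv(ICG)
            T = G[None] @ inv                      # (G^{-1} + C)^{-1}
        if np.any(det <= 0):
            return None
        logdet = float(np.log(det).sum())
        TD = T @ D                                 # (N, q, p)
        A = FtF - np.einsum("nqp,nqr->pr", D, TD)
        b = Ftx - np.einsum("nqp,nq->p", D, (T @ e[..., None])[..., 0])
        c = xtx - float(np.einsum("nq,nq->", e, (T @ e[..., None])[..., 0]))
        return A, b, c, logdet, T

    def criterion(theta):
        G = _theta_to_gamma(theta, q)
        core = _core(G)
        if core is None:
            return 1e12
        A, b, c, logdet, _ = core
        try:
            alpha = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return 1e12
        quad = max(c - float(b @ alpha), 1e-30)
        s2 = quad / (M - p)
        sign, logdet_A = np.linalg.slogdet(A)
        return (M - p) * np.log(s2) + logdet + logdet_A

    rng = np.random.default_rng(seed)
    n_free = 3 if q == 2 else 1
    inits = [np.zeros(n_free)]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.normal(0, 1.0, size=n_free))
    best = None
    for x0 in inits:
        res = minimize(criterion, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        elif abs(res.fun - best.fun) < 1e-6:
            break  # independent starts agree; further restarts add nothing
    if best is None or not np.isfinite(best.fun):
        raise FitError("REML optimization failed in every restart")

    G = _theta_to_gamma(best.x, q)
    A, b, c, logdet, T = _core(G)
    alpha = np.linalg.solve(A, b)
    quad = max(c - float(b @ alpha), 1e-30)
    s2 = quad / (M - p)
    crit = float(best.fun)
    Gfull = s2 * G
    var_int = float(Gfull[0, 0])
    var_slope = float(Gfull[1, 1]) if q == 2 else 0.0
    if q == 2 and var_int > 0 and var_slope > 0:
        corr = float(Gfull[0, 1] / np.sqrt(var_int * var_slope))
    else:
        corr = 0.0
    notes = []
    used_slope = random_slope
    if random_slope and var_slope < 1e-8 * max(var_int, s2):
        notes.append("random-slope variance at boundary")

    # BLUPs: b_i = G Z_i' V_i^{-1} (x_i - F_i alpha)  (sigma2 cancels); the
    # push-through identity gives the cancellation-free form b_i = T_i g_i
    # with T_i = (G^{-1} + C_i)^{-1} and g_i = Z_i'(x_i - F_i alpha)
    g_i = e - (D @ alpha)
    blup_rows = (T @ g_i[..., None])[..., 0]
    cols = ["intercept", "slope"][:q]
    blups = pd.DataFrame(blup_rows, index=pd.Index(subj_order, name="subject_id"), columns=cols)
    blups = blups.reindex(cohort.baseline.index.intersection(blups.index))

    const = (M - p) * (1 + np.log(2 * np.pi))
    return LmmFit(
        fixed_effects=pd.Series(alpha, index=fixed_names),
        var_intercept=var_int,
        var_slope=var_slope,
        re_correlation=corr,
        resid_var=float(s2),
        blups=blups,
        used_slope=used_slope,
        reml_loglik=float(-0.5 * (crit + const)),
        time_center_days=t_center,
        notes=notes,
    )


# --------------------------------------------------------------------- #
# Pooled GEE with visit-specific coefficients
# --------------------------------------------------------------------- #

def fit_pooled_gee(cohort: Cohort, tv_covariates=None, baseline_covariates=None,
                   min_visit_obs: int = 10) -> GeeFit:
    """Visit-stratified logistic GEE under working independence.

    The mean model is fully stratified by visit (visit-specific intercepts,
    exposure coefficients and covariate effects), so point estimates coincide
    with the separate per-visit MLEs; the subject-clustered sandwich
    covariance ties them together and yields a Wald test of
    H0: beta_1 = ... = beta_n with n-1 degrees of freedom.
    """
    if cohort.exposure_scale != "ln":
        raise FitError("fit_pooled_gee expects an ln-scale cohort")
    if tv_covariates is None:
        tv_covariates = list(cohort.model_tv_covariates())
    if baseline_covariates is None:
        baseline_covariates = list(cohort.model_baseline_covariates())
    d = cohort.merged()
    visits = sorted(d["visit"].unique())
    notes = []
    for v in visits:
        n_v = int((d["visit"] == v).sum())
        if n_v < min_visit_obs:
            notes.append(f"visit {v} has only {n_v} observations")
            warnings.warn(notes[-1])

    base = build_design(d, [*tv_covariates, *baseline_covariates], intercept=True)
    blocks, names = [], []
    expo = d["exposure"].to_numpy(dtype=float)
    for v in visits:
        ind = (d["visit"] == v).to_numpy(dtype=float)
        blocks.append(base.to_numpy(dtype=float) * ind[:, None])
        names.extend([f"{c}_v{v}" for c in base.columns])
        blocks.append((expo * ind)[:, None])
        names.append(f"exposure_v{v}")
    X = np.hstack(blocks)
    y = d["outcome"].to_numpy(dtype=float)
    fit = fit_logistic(y, pd.DataFrame(X, columns=names))

    # subject-clustered sandwich
    beta = fit.coefficients.to_numpy()
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    bread = np.linalg.inv((X.T * w) @ X)
    score_rows = X * (y - mu)[:, None]
    clusters = pd.DataFrame(score_rows).groupby(d["subject_id"].to_numpy()).sum().to_numpy()
    meat = clusters.T @ clusters
    V = bread @ meat @ bread
    V = 0.5 * (V + V.T)
    sandwich = pd.DataFrame(V, index=names, columns=names)

    expo_names = [f"exposure_v{v}" for v in visits]
    bv = fit.coefficients[expo_names]
    sv = pd.Series(np.sqrt(np.diag(sandwich.loc[expo_names, expo_names])), index=expo_names)
    n_visits = len(visits)
    if n_visits >= 2:
        C = np.zeros((n_visits - 1, len(names)))
        for k in range(n_visits - 1):
            C[k, names.index(expo_names[k])] = 1.0
            C[k, names.index(expo_names[k + 1])] = -1.0
        mid = C @ V @ C.T
        try:
            diff = C @ beta
            stat = float(diff @ np.linalg.solve(mid, diff))
        except np.linalg.LinAlgError as exc:
            raise FitError("singular sandwich covariance in equality test") from exc
        df = n_visits - 1
        p_eq = float(stats.chi2.sf(stat, df))
    else:
        stat, df, p_eq = float("nan"), 0, float("nan")
        notes.append("single visit: equality test skipped")
    return GeeFit(
        visit_betas=pd.Series(bv.to_numpy(), index=expo_names),
        visit_se=sv,
        params=fit.coefficients,
        sandwich_cov=sandwich,
        n_clusters=int(d["subject_id"].nunique()),
        equality_stat=stat,
        equality_df=df,
        equality_p=p_eq,
        notes=notes,
    )
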