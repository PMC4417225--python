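"""Method 9: functional logistic regression via sparse FPCA.

The ln-exposure process is modeled as X_i(t) = mu(t) + sum_l xi_il phi_l(t)
observed with noise at each subject's few irregular visit times.  The mean is
a penalized B-spline smooth of the pooled points; the covariance surface is a
tensor-product smooth of raw residual cross-products over off-diagonal pairs;
the measurement-error variance comes from the smoothed diagonal minus the
surface's diagonal; eigenfunctions/eigenvalues come from a quadrature-weighted
eigendecomposition of the discretized surface; and FPC scores are best linear
predictors (conditional expectations under a Gaussian working model) given
each subject's own observations — the standard approach for sparse
longitudinal designs.  The outcome model is then a logistic regression on the
leading L scores with an L-df likelihood-ratio test of any exposure effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .cohort import Cohort
from .design import build_design
from .regression import FitError, fit_logistic
from .results import MethodResult

__all__ = ["FpcaFit", "fpca_pace", "select_fpca_model", "functional_logistic_model"]


@dataclass
class FpcaFit:
    grid: np.ndarray
    mean_function: np.ndarray
    eigenfunctions: np.ndarray      # (grid_size, L_max)
    eigenvalues: np.ndarray         # descending, >= 0
    noise_var: float
    scores: pd.DataFrame            # subjects x L_max
    n_basis: int
    fraction_variance: np.ndarray   # cumulative share of total eigenvalue mass
    notes: list = field(default_factory=list)


# ------------------------------------------------------------------ #
# spline helpers
# ------------------------------------------------------------------ #

def _basis(n_basis: int, lo: float, hi: float):
    """Cubic B-spline basis with ``n_basis`` columns on [lo, hi]."""
    n_interior = n_basis - 4
    if n_interior < 0:
        raise FitError("n_basis must be >= 4 for a cubic basis")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    kn = np.concatenate([[lo] * 4, interior, [hi] * 4])
    return kn


def _eval_basis(kn, t):
    return BSpline.design_matrix(np.clip(t, kn[0], kn[-1]), kn, 3).toarray()


def _pen2(K: int) -> np.ndarray:
    D = np.diff(np.eye(K), n=2, axis=0)
    return D.T @ D


def _smooth_1d(t, y, kn, lambdas=np.logspace(-4, 4, 9)):
    """Penalized B-spline fit with GCV over a log-spaced lambda grid."""
    B = _eval_basis(kn, t)
    K = B.shape[1]
    S = _pen2(K)
    BtB = B.T @ B
    Bty = B.T @ y
    best = None
    n = len(y)
    for lam in lambdas:
        A = BtB + lam * S + 1e-10 * np.eye(K)
        coef = np.linalg.solve(A, Bty)
        Ainv = np.linalg.inv(A)
        edf = float(np.sum(Ainv * BtB))
        rss = float(np.sum((y - B @ coef) ** 2))
        gcv = n * rss / max(n - edf, 1.0) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, coef, lam)
    return best[1], best[2]


# ------------------------------------------------------------------ #
# PACE
# ------------------------------------------------------------------ #

def fpca_pace(cohort: Cohort, n_basis: int = 9, grid_size: int = 51,
              max_components: int = 6, min_pooled: int = 50) -> FpcaFit:
    """Sparse FPCA with conditional-expectation scores."""
    if cohort.exposure_scale != "ln":
        raise FitError("fpca_pace expects an ln-scale cohort")
    d = cohort.data
    if len(d) < min_pooled:
        raise FitError(f"need >= {min_pooled} pooled observations, got {len(d)}")
    t = d["time_days"].to_numpy(dtype=float) / 7.0
    x = d["exposure"].to_numpy(dtype=float)
    lo, hi = float(t.min()), float(t.max())
    kn = _basis(n_basis, lo, hi)
    grid = np.linspace(lo, hi, grid_size)
    Bg = _eval_basis(kn, grid)

    # mean function
    mu_coef, _ = _smooth_1d(t, x, kn)
    mu_grid = Bg @ mu_coef
    resid = x - _eval_basis(kn, t) @ mu_coef

    # raw off-diagonal cross-products, grouped by subject
    sid = d["subject_id"].to_numpy()
    order = np.argsort(sid, kind="stable")
    rows_t, rows_s, rows_v = [], [], []
    diag_t, diag_v = t, resid**2
    _, starts = np.unique(sid[order], return_index=True)
    bounds = np.append(np.sort(starts), len(sid))
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = order[a:b]
        if len(idx) < 2:
            continue
        ti, ri = t[idx], resid[idx]
        J, Kk = np.meshgrid(np.arange(len(idx)), np.arange(len(idx)), indexing="ij")
        off = J != Kk
        rows_t.append(ti[J[off]])
        rows_s.append(ti[Kk[off]])
        rows_v.append((ri[J[off]] * ri[Kk[off]]))
    ts = np.concatenate(rows_t)
    ss = np.concatenate(rows_s)
    vv = np.concatenate(rows_v)

    # tensor-product smooth of the covariance surface
    Bt = _eval_basis(kn, ts)
    Bs = _eval_basis(kn, ss)
    K = Bt.shape[1]
    rowsym = 0.5 * (np.einsum("ij,ik->ijk", Bt, Bs) + np.einsum("ij,ik->ijk", Bs, Bt))
    A = rowsym.reshape(len(ts), K * K)
    S = _pen2(K)
    P = np.kron(S, np.eye(K)) + np.kron(np.eye(K), S)
    AtA = A.T @ A
    Atv = A.T @ vv
    best = None
    for lam in np.logspace(-4, 5, 10):
        M = AtA + lam * P + 1e-8 * np.eye(K * K)
        coef = np.linalg.solve(M, Atv)
        edf = float(np.sum(np.linalg.inv(M) * AtA))
        rss = float(np.sum((vv - A @ coef) ** 2))
        gcv = len(vv) * rss / max(len(vv) - edf, 1.0) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, coef)
    Cmat = best[1].reshape(K, K)
    Cmat = 0.5 * (Cmat + Cmat.T)
    C_grid = Bg @ Cmat @ Bg.T

    # noise variance: smoothed diagonal minus surface diagonal, averaged over
    # the central half of the time range
    var_coef, _ = _smooth_1d(diag_t, diag_v, kn)
    V_grid = Bg @ var_coef
    span = hi - lo
    central = (grid >= lo + 0.25 * span) & (grid <= hi - 0.25 * span)
    sigma2 = float(np.mean(np.maximum(V_grid[central] - np.diag(C_grid)[central], 0.0)))

    # quadrature-weighted eigendecomposition
    w = np.full(grid_size, (hi - lo) / (grid_size - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    sw = np.sqrt(w)
    Msym = sw[:, None] * C_grid * sw[None, :]
    evals, evecs = np.linalg.eigh(Msym)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    n_neg = int((evals < 0).sum())
    notes = []
    if n_neg:
        notes.append(f"covariance surface truncated: {n_neg} negative eigenvalues set to 0")
        warnings.warn(notes[-1])
    evals = np.maximum(evals, 0.0)
    keep = min(max_components, int((evals > 1e-10 * max(evals[0], 1e-12)).sum()))
    keep = max(keep, 1)
    lam_l = evals[:keep]
    phi = evecs[:, :keep] / sw[:, None]
    # deterministic sign: positive integral (fall back to positive max element)
    for l in range(keep):
        s = np.sum(phi[:, l] * w)
        if abs(s) < 1e-8:
            s = phi[np.argmax(np.abs(phi[:, l])), l]
        if s < 0:
            phi[:, l] *= -1

    # conditional-expectation scores on each subject's own time points
    sigma2_eff = max(sigma2, 1e-8)
    scores = np.zeros((cohort.n_subjects, keep))
    ids = cohort.baseline.index.to_numpy()
    pos = {s: i for i, s in enumerate(ids)}
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = order[a:b]
        ti = t[idx]
        ri = resid[idx]
        Phi_i = np.column_stack([np.interp(ti, grid, phi[:, l]) for l in range(keep)])
        Sig = Phi_i @ np.diag(lam_l) @ Phi_i.T + sigma2_eff * np.eye(len(idx))
        xi = np.diag(lam_l) @ Phi_i.T @ np.linalg.solve(Sig, ri)
        scores[pos[sid[idx[0]]]] = xi
    score_df = pd.DataFrame(scores, index=pd.Index(ids, name="subject_id"),
                            columns=[f"fpc_{l+1}" for l in range(keep)])
    total = evals.sum()
    frac = np.cumsum(lam_l) / total if total > 0 else np.zeros(keep)
    return FpcaFit(
        grid=grid, mean_function=mu_grid, eigenfunctions=phi, eigenvalues=lam_l,
        noise_var=sigma2, scores=score_df, n_basis=n_basis,
        fraction_variance=frac, notes=notes,
    )


# ------------------------------------------------------------------ #
# model selection
# ------------------------------------------------------------------ #

def _process_loglik(cohort: Cohort, fit: FpcaFit, L: int) -> tuple[float, int]:
    """Pooled Gaussian log-likelihood of the observations under the fitted
    L-component process, and total observation count."""
    d = cohort.data
    t = d["time_days"].to_numpy(dtype=float) / 7.0
    x = d["exposure"].to_numpy(dtype=float)
    sid = d["subject_id"].to_numpy()
    mu_at = np.interp(t, fit.grid, fit.mean_function)
    r = x - mu_at
    s2 = max(fit.noise_var, 1e-8)
    ll = 0.0
    order = np.argsort(sid, kind="stable")
    _, starts = np.unique(sid[order], return_index=True)
    bounds = np.append(np.sort(starts), len(sid))
    lam = fit.eigenvalues[:L]
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = order[a:b]
        ti, ri = t[idx], r[idx]
        if L > 0:
            Phi_i = np.column_stack(
                [np.interp(ti, fit.grid, fit.eigenfunctions[:, l]) for l in range(L)]
            )
            Sig = Phi_i @ np.diag(lam) @ Phi_i.T + s2 * np.eye(len(idx))
        else:
            Sig = s2 * np.eye(len(idx))
        sign, logdet = np.linalg.slogdet(Sig)
        ll += -0.5 * (len(idx) * np.log(2 * np.pi) + logdet + ri @ np.linalg.solve(Sig, ri))
    return float(ll), len(d)


def select_fpca_model(cohort: Cohort, n_basis_grid=(5, 7, 9, 11), l_grid=(1, 2, 3),
                      criterion: str = "modified_bic", n_folds: int = 10,
                      seed: int = 0, grid_size: int = 51):
    """Choose (n_basis, L) by modified BIC or approximate leave-curve-out CV.

    ``locv`` approximates leave-one-curve-out with ``n_folds`` subject folds:
    the mean/covariance model is refit without each fold and the held-out
    subjects' observations are scored by their conditional-expectation
    reconstruction error.  ``modified_bic`` is the pooled marginal Gaussian
    log-likelihood penalized by half the free-parameter count times
    log(total observations).
    """
    if not len(n_basis_grid) or not len(l_grid):
        raise FitError("candidate grids must be non-empty")
    rows = []
    if criterion == "modified_bic":
        for nb in n_basis_grid:
            fit = fpca_pace(cohort, n_basis=nb, grid_size=grid_size)
            for L in l_grid:
                Lc = min(L, fit.scores.shape[1])
                ll, n_obs = _process_loglik(cohort, fit, Lc)
                m = nb * (1 + Lc) + Lc + 1
                val = ll - 0.5 * m * np.log(n_obs)
                rows.append({"n_basis": nb, "L": L, "criterion": val})
        table = pd.DataFrame(rows)
        best = table.loc[table["criterion"].idxmax()]
    elif criterion == "locv":
        rng = np.random.default_rng(seed)
        ids = cohort.baseline.index.to_numpy()
        folds = rng.permutation(len(ids)) % n_folds
        for nb in n_basis_grid:
            errors = {L: 0.0 for L in l_grid}
            for f in range(n_folds):
                train = cohort.subset(ids[folds != f])
                test = cohort.subset(ids[folds == f])
                try:
                    fit = fpca_pace(train, n_basis=nb, grid_size=grid_size)
                except FitError:
                    continue
                d = test.data
                t = d["time_days"].to_numpy(dtype=float) / 7.0
                x = d["exposure"].to_numpy(dtype=float)
                sidv = d["subject_id"].to_numpy()
                mu_at = np.interp(t, fit.grid, fit.mean_function)
                r = x - mu_at
                s2 = max(fit.noise_var, 1e-8)
                for L in l_grid:
                    Lc = min(L, fit.scores.shape[1])
                    lam = fit.eigenvalues[:Lc]
                    for sid_u in np.unique(sidv):
                        m_i = sidv == sid_u
                        ti, ri = t[m_i], r[m_i]
                        Phi_i = np.column_stack(
                            [np.interp(ti, fit.grid, fit.eigenfunctions[:, l])
                             for l in range(Lc)]
                        )
                        Sig = Phi_i @ np.diag(lam) @ Phi_i.T + s2 * np.eye(len(ti))
                        xi = np.diag(lam) @ Phi_i.T @ np.linalg.solve(Sig, ri)
                        errors[L] += float(np.sum((ri - Phi_i @ xi) ** 2))
            for L in l_grid:
                rows.append({"n_basis": nb, "L": L, "criterion": errors[L]})
        table = pd.DataFrame(rows)
        best = table.loc[table["criterion"].idxmin()]
    else:
        raise ValueError("criterion must be 'modified_bic' or 'locv'")
    return int(best["n_basis"]), int(best["L"]), table


# ------------------------------------------------------------------ #
# outcome model
# ------------------------------------------------------------------ #

def functional_logistic_model(cohort: Cohort, covariates=None, L=2,
                              fpca: FpcaFit | None = None,
                              n_basis: int = 9, grid_size: int = 51) -> MethodResult:
    """Logistic regression on the leading L FPC scores, with an L-df LRT.

    ``L='auto'`` selects (n_basis, L) by modified BIC first.  The time-varying
    coefficient beta(t) = sum_l beta_l phi_l(t) is returned in the notes
    metadata with plug-in pointwise bands that ignore FPCA estimation
    uncertainty (flagged as such).
    """
    notes = []
    if L == "auto":
        n_basis, L, _ = select_fpca_model(cohort)
        notes.append(f"modified BIC selected n_basis={n_basis}, L={L}")
    if fpca is None:
        fpca = fpca_pace(cohort, n_basis=n_basis, grid_size=grid_size)
    if L > fpca.scores.shape[1]:
        raise FitError(f"L={L} exceeds the {fpca.scores.shape[1]} available components")
    bl = list(cohort.model_baseline_covariates()) if covariates is None else [
        c for c in covariates if c in cohort.baseline.columns and c != "outcome"
    ]
    score_cols = [f"fpc_{l+1}" for l in range(L)]
    frame = fpca.scores[score_cols].join(cohort.baseline[bl + ["outcome"]]) if L else \
        cohort.baseline[bl + ["outcome"]].copy()
    y = frame["outcome"].to_numpy(dtype=float)
    X0 = build_design(frame, bl, intercept=True)
    fit0 = fit_logistic(y, X0)
    if L == 0:
        tests = pd.DataFrame({"statistic": [0.0], "df": [0], "p": [1.0]}, index=["score_lrt"])
        return MethodResult(method="functional_logistic",
                            estimates=pd.DataFrame(columns=["coef", "se", "or", "ci_low",
                                                            "ci_high", "p"]),
                            global_tests=tests, n_used=len(frame),
                            notes=notes + ["L=0: covariate-only model"])
    X1 = build_design(frame, score_cols + bl, intercept=True)
    fit1 = fit_logistic(y, X1)
    lrt = max(2.0 * (fit1.loglik - fit0.loglik), 0.0)
    tests = pd.DataFrame(
        {"statistic": [lrt], "df": [L], "p": [float(stats.chi2.sf(lrt, L))]},
        index=["score_lrt"],
    )
    beta_l = fit1.coefficients[score_cols].to_numpy()
    beta_t = fpca.eigenfunctions[:, :L] @ beta_l
    cov_b = fit1.covariance.loc[score_cols, score_cols].to_numpy()
    band = np.sqrt(np.einsum("ij,jk,ik->i", fpca.eigenfunctions[:, :L], cov_b,
                             fpca.eigenfunctions[:, :L]))
    notes.append("beta(t) plug-in bands ignore FPCA estimation uncertainty")
    result = MethodResult(
        method="functional_logistic",
        estimates=MethodResult.estimate_rows(fit1.summary(), score_cols),
        global_tests=tests,
        n_used=len(frame),
        notes=notes + list(fit1.notes) + list(fpca.notes),
    )
    result.beta_curve = pd.DataFrame(
        {"t_weeks": fpca.grid, "beta": beta_t, "se_plugin": band}
    )
    return result
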