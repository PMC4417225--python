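"""Methods 7 and 8: unsupervised grouping of exposure profiles.

Method 7 fits K-component multivariate Gaussian mixtures to the complete-case
wide exposure matrix and picks K by BIC (convention: 2*loglik - m*log N,
larger is better).  Method 8 summarizes each subject's (time, value) points by
a least-squares line, evaluates it on a common grid and k-means-clusters the
resulting vectors (the centroids approximate principal points); it tolerates
unbalanced cohorts and can cluster covariate-residualized curves.  Either
clustering is then related to the outcome by a chi-square independence test
(df = K-1) and a logistic regression on cluster indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .cohort import Cohort, pivot_wide, residualize_exposure
from .design import build_design
from .regression import FitError, fit_logistic
from .results import MethodResult

__all__ = ["ClusterModel", "gmm_cluster", "functional_cluster", "cluster_association"]


@dataclass
class ClusterModel:
    kind: str                       # "gmm" | "functional"
    k: int
    assignment: pd.Series           # cluster index (1..k) per used subject
    component_summary: pd.DataFrame  # per-cluster per-visit means / centroid curves
    selection: pd.DataFrame         # criterion value per candidate k
    seed: int
    n_used: int
    grid: np.ndarray | None = None
    notes: list = field(default_factory=list)

    def covariate_screen(self, cohort: Cohort) -> pd.DataFrame:
        """Per-covariate dependence of the clustering (diagnostic).

        Continuous covariates: one-way ANOVA across clusters; binary/categorical:
        chi-square of independence.
        """
        rows = []
        lab = self.assignment
        base = cohort.baseline.loc[lab.index]
        subj_tv = cohort.data.groupby("subject_id")[list(cohort.tv_covariates)].mean()
        frame = base.join(subj_tv, how="left")
        for cov in [*cohort.baseline_covariates, *cohort.tv_covariates]:
            x = frame[cov]
            vals = x.dropna()
            if vals.nunique() <= 5:
                tab = pd.crosstab(lab.loc[vals.index], vals)
                if tab.shape[0] > 1 and tab.shape[1] > 1:
                    stat, p, dof, _ = stats.chi2_contingency(tab, correction=False)
                    rows.append({"covariate": cov, "test": "chi2", "statistic": stat, "p": p})
            else:
                groups = [vals[lab.loc[vals.index] == c] for c in sorted(lab.unique())]
                groups = [g for g in groups if len(g) > 1]
                if len(groups) > 1:
                    stat, p = stats.f_oneway(*groups)
                    rows.append({"covariate": cov, "test": "anova", "statistic": stat, "p": p})
        return pd.DataFrame(rows)


def _relabel_by_level(labels: np.ndarray, level: np.ndarray, k: int) -> np.ndarray:
    """Map raw labels to 1..k ordered by ascending overall mean level."""
    order = np.argsort([level[labels == c].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[labels]


def gmm_cluster(cohort: Cohort, k_max: int = 3, seed: int = 0,
                ridge_scale: float = 1e-6, k_min: int = 1) -> ClusterModel:
    """Gaussian-mixture clustering of the complete-case exposure vectors.

    Candidate K runs from ``k_min`` to ``k_max`` (pin both to force a K).
    """
    if cohort.exposure_scale != "ln":
        raise FitError("gmm_cluster expects an ln-scale cohort")
    X, _, ids = pivot_wide(cohort, require_complete=True)
    n, d = X.shape
    if n < 10 * k_max:
        raise FitError(
            f"Gaussian mixture needs a balanced complete-case matrix with >= {10 * k_max} "
            f"subjects, got {n}; this method requires complete exposure vectors"
        )
    reg = ridge_scale * np.trace(np.cov(X.T, bias=True)) / d
    fits, rows = {}, []
    for K in range(k_min, k_max + 1):
        gm = GaussianMixture(
            n_components=K, covariance_type="full", n_init=10,
            init_params="kmeans", random_state=seed, reg_covar=max(reg, 1e-10),
        ).fit(X)
        loglik = float(gm.score(X) * n)
        m = (K - 1) + K * d + K * d * (d + 1) // 2
        bic = 2.0 * loglik - m * np.log(n)
        fits[K] = gm
        rows.append({"k": K, "loglik": loglik, "n_params": m, "bic": bic})
    sel = pd.DataFrame(rows).set_index("k")
    k_best = int(sel["bic"].idxmax())
    gm = fits[k_best]
    raw = gm.predict(X)
    level = X.mean(axis=1)
    labels = _relabel_by_level(raw, level, k_best) if k_best > 1 else np.ones(n, dtype=int)
    assignment = pd.Series(labels, index=pd.Index(ids, name="subject_id"), name="cluster")
    means = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(1, k_best + 1)],
        index=pd.Index(range(1, k_best + 1), name="cluster"),
        columns=[f"visit_{j}" for j in range(1, d + 1)],
    )
    return ClusterModel(
        kind="gmm", k=k_best, assignment=assignment, component_summary=means,
        selection=sel, seed=seed, n_used=n,
        notes=[f"BIC (2*loglik - m*logN, larger better) selected K={k_best}"],
    )


def functional_cluster(cohort: Cohort, k: int = 2, residualize: bool = False,
                       covariate_names=None, grid_size: int = 20,
                       seed: int = 0) -> ClusterModel:
    """k-means on per-subject line fits evaluated on a common time grid.

    With at most a handful of irregular points per subject a line is the
    richest identifiable curve; its grid evaluation turns each subject into a
    fixed-length vector whose k-means centroids approximate principal points.
    Balance is not required; single-visit subjects contribute constant curves.
    """
    if cohort.exposure_scale != "ln":
        raise FitError("functional_cluster expects an ln-scale cohort")
    if k >= cohort.n_subjects / 10:
        raise FitError("k must be < N/10")
    work = cohort
    notes = []
    if residualize:
        if covariate_names is None:
            covariate_names = [*cohort.model_tv_covariates(), *cohort.model_baseline_covariates()]
        work = residualize_exposure(cohort, list(covariate_names))
        notes.append(f"clustered residual curves (removed: {list(covariate_names)})")

    d = work.data
    t = d["time_days"].to_numpy(dtype=float) / 7.0
    lo, hi = float(t.min()), float(t.max())
    grid = np.linspace(lo, hi, grid_size)
    curves, ids = [], []
    for sid, g in d.groupby("subject_id", sort=True):
        tt = g["time_days"].to_numpy(dtype=float) / 7.0
        xx = g["exposure"].to_numpy(dtype=float)
        if len(g) >= 2:
            slope, intercept = np.polyfit(tt, xx, 1)
            curves.append(intercept + slope * grid)
        else:
            curves.append(np.full(grid_size, xx[0]))
        ids.append(sid)
    V = np.asarray(curves)
    km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(V)
    labels = _relabel_by_level(km.labels_, V.mean(axis=1), k)
    assignment = pd.Series(labels, index=pd.Index(ids, name="subject_id"), name="cluster")
    centroids = pd.DataFrame(
        [V[labels == c].mean(axis=0) for c in range(1, k + 1)],
        index=pd.Index(range(1, k + 1), name="cluster"),
        columns=[f"t_{j}" for j in range(grid_size)],
    )
    inertia = pd.DataFrame({"k": [k], "inertia": [float(km.inertia_)]}).set_index("k")
    return ClusterModel(
        kind="functional", k=k, assignment=assignment, component_summary=centroids,
        selection=inertia, seed=seed, n_used=len(ids), grid=grid, notes=notes,
    )


def cluster_association(model: ClusterModel, cohort: Cohort,
                        covariates=None) -> MethodResult:
    """Relate a clustering to the outcome.

    (a) chi-square independence test on the K x 2 cluster-by-outcome table
    (df = K-1, uncorrected); (b) logistic regression of the outcome on K-1
    cluster indicators plus baseline covariates, odds ratios versus cluster 1.
    """
    lab = model.assignment.rename("cluster")
    y = cohort.baseline.loc[lab.index, "outcome"]
    tab = pd.crosstab(lab, y)
    notes = list(model.notes)
    tests_rows = {}
    k = model.k
    if tab.shape[1] < 2 or (tab == 0).any(axis=None):
        # degenerate table: fall back to an exact test when 2x2
        if tab.shape == (2, 2):
            _, p_exact = stats.fisher_exact(tab.to_numpy())
            tests_rows["cluster_outcome_fisher"] = {"statistic": np.nan, "df": np.nan,
                                                    "p": float(p_exact)}
            notes.append("degenerate table: Fisher exact test used")
        else:
            notes.append("degenerate cluster-by-outcome table: chi-square unavailable")
    if tab.shape[1] == 2 and "cluster_outcome_fisher" not in tests_rows and k > 1:
        stat, p, dof, expected = stats.chi2_contingency(tab, correction=False)
        if (expected < 5).any():
            notes.append("chi-square expected count < 5 in some cell")
        tests_rows["cluster_outcome_chi2"] = {"statistic": float(stat), "df": int(k - 1),
                                              "p": float(p)}

    bl = list(cohort.model_baseline_covariates()) if covariates is None else [
        c for c in covariates if c in cohort.baseline.columns and c != "outcome"
    ]
    frame = lab.to_frame().join(cohort.baseline[bl + ["outcome"]])
    terms = []
    for c in range(2, k + 1):
        name = f"cluster_{c}"
        frame[name] = (frame["cluster"] == c).astype(float)
        terms.append(name)
    est = pd.DataFrame(columns=["coef", "se", "or", "ci_low", "ci_high", "p"])
    if terms:
        X = build_design(frame, terms + bl, intercept=True)
        fit = fit_logistic(frame["outcome"].to_numpy(dtype=float), X)
        est = MethodResult.estimate_rows(fit.summary(), terms)
        notes.extend(fit.notes)
    sizes = lab.value_counts()
    if (sizes < 0.05 * len(lab)).any():
        notes.append(
            f"tiny cluster: sizes {sizes.sort_index().tolist()}; stage-2 estimates unreliable"
        )
    return MethodResult(
        method=f"{model.kind}_cluster_association",
        estimates=est,
        global_tests=pd.DataFrame.from_dict(tests_rows, orient="index"),
        n_used=len(lab),
        notes=notes,
    )
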