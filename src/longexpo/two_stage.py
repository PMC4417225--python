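"""Method 5: two-stage mixed-effects summaries of the exposure trajectory.

Stage 1 fits a linear mixed model of the ln exposure on gestational time with
a random intercept and (by default) a random slope; stage 2 relates the
outcome to each subject's predicted random effects (BLUPs), either directly
or through a k-means clustering of the (intercept, slope) plane.

Stage-2 standard errors treat the BLUPs as known covariates; the stage-1
estimation uncertainty is not propagated, which can understate stage-2
uncertainty.  The simulation harness measures this rather than hiding it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import Cohort
from .design import build_design
from .regression import FitError, fit_lmm, fit_logistic
from .results import MethodResult

__all__ = ["two_stage_blup_model", "two_stage_cluster_model"]

#: |random-effect correlation| above which the slope is judged redundant
DEMOTION_CORR = 0.95
#: critical value (2.5% level) of the 0.5*chi2(1) + 0.5*chi2(2) boundary
#: mixture for testing a random slope against zero; the conservative level
#: means the slope is kept only on strong evidence, since the finite-sample
#: null distribution of the REML improvement runs slightly heavy
SLOPE_LRT_CUTOFF = 6.68


def _stage1(cohort: Cohort, slope_policy: str, seed: int = 0):
    if slope_policy not in {"auto", "force_slope", "intercept_only"}:
        raise ValueError("slope_policy must be auto, force_slope or intercept_only")
    notes = []
    if slope_policy == "intercept_only":
        lmm = fit_lmm(cohort, random_slope=False, seed=seed)
        return lmm, notes
    lmm = fit_lmm(cohort, random_slope=True, seed=seed)
    if slope_policy == "auto":
        # demote when the random slope is redundant: near-degenerate
        # correlation with the intercept, or no significant REML improvement
        # over the intercept-only model (boundary-mixture LRT)
        lmm0 = fit_lmm(cohort, random_slope=False, seed=seed)
        lrt = max(2.0 * (lmm.reml_loglik - lmm0.reml_loglik), 0.0)
        boundary = any("boundary" in n for n in lmm.notes)
        if abs(lmm.re_correlation) > DEMOTION_CORR or boundary or lrt < SLOPE_LRT_CUTOFF:
            if abs(lmm.re_correlation) > DEMOTION_CORR:
                why = f"|re correlation| = {abs(lmm.re_correlation):.3f} > {DEMOTION_CORR}"
            elif boundary:
                why = "slope variance at boundary"
            else:
                why = f"REML improvement LRT = {lrt:.2f} < {SLOPE_LRT_CUTOFF}"
            notes.append(f"random slope demoted: {why}")
            lmm = lmm0
    return lmm, notes


def two_stage_blup_model(cohort: Cohort, covariates=None,
                         slope_policy: str = "auto", seed: int = 0) -> MethodResult:
    """Logistic regression of the outcome on stage-1 BLUPs."""
    lmm, notes = _stage1(cohort, slope_policy, seed)
    bl = list(cohort.model_baseline_covariates()) if covariates is None else [
        c for c in covariates if c in cohort.baseline.columns and c != "outcome"
    ]
    frame = lmm.blups.rename(columns={"intercept": "blup_intercept", "slope": "blup_slope"})
    frame = frame.join(cohort.baseline[bl + ["outcome"]])
    terms = [c for c in ("blup_intercept", "blup_slope") if c in frame.columns]
    X = build_design(frame, terms + bl, intercept=True)
    fit = fit_logistic(frame["outcome"].to_numpy(dtype=float), X)
    notes = notes + [f"stage 1: {'random intercept + slope' if lmm.used_slope else 'random intercept only'}"]
    return MethodResult(
        method="two_stage_blup",
        estimates=MethodResult.estimate_rows(fit.summary(), terms),
        n_used=len(frame),
        notes=notes + list(fit.notes),
    )


def two_stage_cluster_model(cohort: Cohort, covariates=None, k: int = 2,
                            seed: int = 0) -> tuple[MethodResult, pd.Series]:
    """Cluster standardized (intercept, slope) BLUPs; stage-2 on cluster index.

    Clusters are relabeled by ascending mean intercept so the highest index is
    the "greater predicted intercept" group; odds ratios are versus cluster 1.
    """
    if k < 2 or k >= cohort.n_subjects / 10:
        raise FitError("k must satisfy 2 <= k < N/10")
    lmm, _ = _stage1(cohort, "force_slope", seed)
    if not lmm.used_slope or "slope" not in lmm.blups.columns:
        raise FitError("cluster model needs a retained random slope; use two_stage_blup_model")
    B = lmm.blups[["intercept", "slope"]].to_numpy()
    Bz = (B - B.mean(axis=0)) / B.std(axis=0, ddof=0)
    km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(Bz)
    raw = km.labels_
    order = np.argsort([B[raw == c, 0].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=lmm.blups.index, name="cluster")

    bl = list(cohort.model_baseline_covariates()) if covariates is None else [
        c for c in covariates if c in cohort.baseline.columns and c != "outcome"
    ]
    frame = labels.to_frame().join(cohort.baseline[bl + ["outcome"]])
    terms = []
    for c in range(2, k + 1):
        name = f"cluster_{c}"
        frame[name] = (frame["cluster"] == c).astype(float)
        terms.append(name)
    X = build_design(frame, terms + bl, intercept=True)
    fit = fit_logistic(frame["outcome"].to_numpy(dtype=float), X)
    notes = list(fit.notes)
    sizes = labels.value_counts()
    if (sizes < 0.05 * len(labels)).any():
        notes.append("tiny cluster (<5% of subjects): stage-2 estimates may be unstable")
    result = MethodResult(
        method="two_stage_cluster",
        estimates=MethodResult.estimate_rows(fit.summary(), terms),
        n_used=len(frame),
        notes=notes,
    )
    return result, labels
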