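"""The four standard disease-risk models.

Method 1  multiple logistic regression with all visit exposures simultaneously
          (complete cases only), optionally stabilized by the AR(1) Gaussian
          shrinkage prior;
Method 2  parallel per-visit cross-sectional logistic models, optional
          Bonferroni correction, plus the GEE joint equality test;
Method 3  logistic regression on the subject mean ln exposure (the ln of the
          geometric mean on the raw scale), averaged time-varying covariates;
Method 4  logistic regression on the subject maximum ln exposure with the
          argmax visit's time-varying covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .design import build_design
from .regression import FitError, fit_logistic, fit_map_logistic, fit_pooled_gee
from .results import MethodResult

__all__ = [
    "multiple_logistic_model",
    "cross_sectional_models",
    "mean_summary_model",
    "max_summary_model",
]


def _check_ln(cohort: Cohort):
    if cohort.exposure_scale != "ln":
        raise FitError("summary models expect an ln-scale cohort")


def _covariate_lists(cohort, covariates):
    if covariates is None:
        return list(cohort.model_tv_covariates()), list(cohort.model_baseline_covariates())
    tv = [c for c in covariates if c in cohort.data.columns]
    bl = [c for c in covariates if c in cohort.baseline.columns and c != "outcome"]
    return tv, bl


def _apply_transform(values: np.ndarray, transform) -> np.ndarray:
    """Optional exposure-transform hook (identity by default)."""
    return values if transform is None else transform(values)


def multiple_logistic_model(cohort: Cohort, covariates=None, bayes: bool = False,
                            exposure_transform=None, **map_kwargs) -> MethodResult:
    """All visit exposures entered simultaneously; complete-case subjects only."""
    _check_ln(cohort)
    tv, bl = _covariate_lists(cohort, covariates)
    n_max = cohort.n_max
    complete = cohort.complete_subjects()
    if len(complete) < 10:
        raise FitError(f"only {len(complete)} complete cases; need >= 10")
    sub = cohort.subset(complete)

    d = sub.data.set_index(["subject_id", "visit"])
    parts = {}
    for v in range(1, n_max + 1):
        dv = d.xs(v, level="visit")
        parts[f"exposure_v{v}"] = _apply_transform(
            dv["exposure"].to_numpy(dtype=float), exposure_transform
        )
        for c in tv:
            parts[f"{c}_v{v}"] = dv[c].to_numpy(dtype=float)
    idx = d.xs(1, level="visit").index
    wide = pd.DataFrame(parts, index=idx)
    frame = wide.join(sub.baseline[bl + ["outcome"]])

    X = build_design(frame, [c for c in frame.columns if c != "outcome"], intercept=True)
    y = frame["outcome"].to_numpy(dtype=float)
    expo_cols = [f"exposure_v{v}" for v in range(1, n_max + 1)]
    if bayes:
        fit = fit_map_logistic(y, X, exposure_block=expo_cols, **map_kwargs)
    else:
        fit = fit_logistic(y, X)
    summary = fit.summary()
    return MethodResult(
        method="bayes_multiple_logistic" if bayes else "multiple_logistic",
        estimates=MethodResult.estimate_rows(summary, expo_cols),
        n_used=len(frame),
        notes=list(fit.notes),
    )


def cross_sectional_models(cohort: Cohort, covariates=None, correction: str = "none",
                           exposure_transform=None) -> MethodResult:
    """One logistic model per visit; embeds the GEE joint equality test."""
    _check_ln(cohort)
    if correction not in {"none", "bonferroni"}:
        raise ValueError("correction must be 'none' or 'bonferroni'")
    tv, bl = _covariate_lists(cohort, covariates)
    merged = cohort.merged()
    n_max = cohort.n_max
    rows = []
    notes = []
    total_subjects = set()
    for v in range(1, n_max + 1):
        dv = merged[merged["visit"] == v]
        if dv.empty:
            notes.append(f"visit {v}: no observations")
            continue
        frame = dv.copy()
        frame["exposure"] = _apply_transform(frame["exposure"].to_numpy(dtype=float),
                                             exposure_transform)
        X = build_design(frame, ["exposure", *tv, *bl], intercept=True)
        fit = fit_logistic(frame["outcome"].to_numpy(dtype=float), X)
        row = fit.summary().loc["exposure"].copy()
        row["n_used"] = len(dv)
        row.name = f"visit_{v}"
        rows.append(row)
        total_subjects.update(dv["subject_id"])
    est = pd.DataFrame(rows)
    if correction == "bonferroni":
        est["p_adjusted"] = np.minimum(est["p"] * len(est), 1.0)

    try:
        gee = fit_pooled_gee(cohort, tv_covariates=tv, baseline_covariates=bl)
        tests = pd.DataFrame(
            {"statistic": [gee.equality_stat], "df": [gee.equality_df],
             "p": [gee.equality_p]},
            index=["gee_equality"],
        )
        notes.extend(gee.notes)
    except (FitError, np.linalg.LinAlgError) as exc:
        tests = pd.DataFrame(columns=["statistic", "df", "p"])
        notes.append(f"gee equality test unavailable: {exc}")
    return MethodResult(
        method="cross_sectional",
        estimates=est,
        global_tests=tests,
        n_used=len(total_subjects),
        notes=notes,
    )


def _subject_summaries(cohort: Cohort, tv: list[str]):
    """Per-subject mean/max ln exposure and the matching covariate values."""
    d = cohort.data.sort_values(["subject_id", "visit"])
    g = d.groupby("subject_id", sort=False)
    mean_expo = g["exposure"].mean()
    mean_tv = {c: g[c].mean() for c in tv}
    # max with earliest-visit tie break: first row attaining the max
    idx_max = g["exposure"].idxmax()  # idxmax returns first occurrence
    max_rows = d.loc[idx_max].set_index("subject_id")
    return mean_expo, mean_tv, max_rows


def mean_summary_model(cohort: Cohort, covariates=None, exposure_transform=None) -> MethodResult:
    """Subject-level logistic on the mean ln exposure over available visits.

    On the ln scale the arithmetic mean equals the ln geometric mean of the
    raw concentrations.  Time-varying covariates are averaged per subject
    (a binary time-of-day becomes the subject's proportion).
    """
    _check_ln(cohort)
    tv, bl = _covariate_lists(cohort, covariates)
    mean_expo, mean_tv, _ = _subject_summaries(cohort, tv)
    frame = pd.DataFrame({"exposure_mean": mean_expo})
    for c in tv:
        frame[f"{c}_mean"] = mean_tv[c]
    frame = frame.join(cohort.baseline[bl + ["outcome"]])
    frame["exposure_mean"] = _apply_transform(frame["exposure_mean"].to_numpy(dtype=float),
                                              exposure_transform)
    X = build_design(frame, [c for c in frame.columns if c != "outcome"], intercept=True)
    fit = fit_logistic(frame["outcome"].to_numpy(dtype=float), X)
    return MethodResult(
        method="mean_summary",
        estimates=MethodResult.estimate_rows(fit.summary(), ["exposure_mean"]),
        n_used=len(frame),
        notes=list(fit.notes),
    )


def max_summary_model(cohort: Cohort, covariates=None, exposure_transform=None) -> MethodResult:
    """Subject-level logistic on the maximum ln exposure.

    Time-varying covariates are taken from the visit attaining the maximum;
    ties break to the earliest visit.
    """
    _check_ln(cohort)
    tv, bl = _covariate_lists(cohort, covariates)
    _, _, max_rows = _subject_summaries(cohort, tv)
    frame = pd.DataFrame({"exposure_max": max_rows["exposure"]})
    for c in tv:
        frame[f"{c}_at_max"] = max_rows[c]
    frame = frame.join(cohort.baseline[bl + ["outcome"]])
    frame["exposure_max"] = _apply_transform(frame["exposure_max"].to_numpy(dtype=float),
                                             exposure_transform)
    X = build_design(frame, [c for c in frame.columns if c != "outcome"], intercept=True)
    fit = fit_logistic(frame["outcome"].to_numpy(dtype=float), X)
    return MethodResult(
        method="max_summary",
        estimates=MethodResult.estimate_rows(fit.summary(), ["exposure_max"]),
        n_used=len(frame),
        notes=list(fit.notes),
    )
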