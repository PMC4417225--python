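"""Data model for longitudinal-exposure cohorts.

A :class:`Cohort` holds one row per subject-visit (long format) together with
subject-level outcome and baseline covariates.  Exposure is tracked on either
the raw (positive) or natural-log scale; every downstream model in this
package expects the log scale, matching the usual treatment of right-skewed
biomarker concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "Cohort",
    "IccEstimate",
    "read_cohort_long",
    "write_cohort_long",
    "ln_transform",
    "residualize_exposure",
    "pivot_wide",
    "icc",
    "visit_correlations",
]

#: canonical long-format column names
LONG_COLUMNS = ["subject_id", "outcome", "visit", "time_days", "exposure"]


class CohortError(ValueError):
    """Raised when cohort data violate a structural invariant."""


@dataclass(frozen=True)
class IccEstimate:
    """Intraclass correlation of a repeated biomarker.

    ``icc = between_var / (between_var + within_var)`` from a random-intercept
    model of the log exposure; the confidence interval is a subject-level
    nonparametric bootstrap.
    """

    icc: float
    between_var: float
    within_var: float
    ci_low: float
    ci_high: float
    n_boot: int = 0


@dataclass
class Cohort:
    """Longitudinal exposure cohort.

    Parameters
    ----------
    data : DataFrame
        Long format, one row per subject-visit, columns ``subject_id``,
        ``visit``, ``time_days``, ``exposure`` plus any time-varying covariate
        columns named in ``tv_covariates``.
    baseline : DataFrame
        Indexed by ``subject_id``; must contain a binary ``outcome`` column
        plus any baseline covariate columns named in ``baseline_covariates``.
    exposure_scale : {"raw", "ln"}
    residualized : bool
        True when the exposure column holds residuals from a pooled
        regression on covariates; downstream models then omit those
        covariates.
    """

    data: pd.DataFrame
    baseline: pd.DataFrame
    exposure_scale: str = "raw"
    tv_covariates: tuple[str, ...] = ()
    baseline_covariates: tuple[str, ...] = ()
    residualized: bool = False
    residualized_out: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.tv_covariates = tuple(self.tv_covariates)
        self.baseline_covariates = tuple(self.baseline_covariates)
        self.residualized_out = tuple(self.residualized_out)
        self._validate()

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        d = self.data
        missing = [c for c in ("subject_id", "visit", "time_days", "exposure") if c not in d.columns]
        if missing:
            raise CohortError(f"long data lack required columns: {missing}")
        for c in self.tv_covariates:
            if c not in d.columns:
                raise CohortError(f"time-varying covariate column missing: {c!r}")
        if "outcome" not in self.baseline.columns:
            raise CohortError("baseline frame lacks 'outcome' column")
        for c in self.baseline_covariates:
            if c not in self.baseline.columns:
                raise CohortError(f"baseline covariate column missing: {c!r}")
        y = self.baseline["outcome"]
        if not np.isin(y.dropna().unique(), [0, 1]).all():
            raise CohortError("outcome must be binary 0/1")
        unknown = set(d["subject_id"]) - set(self.baseline.index)
        if unknown:
            raise CohortError(f"visit rows for subjects absent from baseline: {sorted(unknown)[:5]}")
        dup = d.duplicated(subset=["subject_id", "visit"])
        if dup.any():
            pair = d.loc[dup.idxmax(), ["subject_id", "visit"]].tolist()
            raise CohortError(f"duplicate (subject, visit) pair: {tuple(pair)}")
        if (d["time_days"] <= 0).any():
            raise CohortError("time_days must be positive")
        # strictly increasing times within subject, ordered by visit index
        ds = d.sort_values(["subject_id", "visit"])
        grp = ds.groupby("subject_id")["time_days"]
        if (grp.diff().dropna() <= 0).any():
            raise CohortError("observation times not strictly increasing within subject")
        if self.exposure_scale == "raw":
            bad = d.index[d["exposure"] <= 0]
            if len(bad):
                raise CohortError(f"non-positive raw exposure at rows {list(bad[:10])}")
        elif self.exposure_scale == "ln":
            if not np.isfinite(d["exposure"]).all():
                raise CohortError("non-finite ln exposure")
        else:
            raise CohortError(f"unknown exposure_scale {self.exposure_scale!r}")

    # ------------------------------------------------------------------ #
    @property
    def subject_ids(self) -> np.ndarray:
        return self.baseline.index.to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.baseline)

    @property
    def n_max(self) -> int:
        return int(self.data["visit"].max())

    @property
    def outcomes(self) -> pd.Series:
        return self.baseline["outcome"]

    def visits_per_subject(self) -> pd.Series:
        counts = self.data.groupby("subject_id").size()
        return counts.reindex(self.baseline.index, fill_value=0)

    def complete_subjects(self) -> np.ndarray:
        """Subjects observed at every visit index up to ``n_max``."""
        counts = self.visits_per_subject()
        return counts.index[counts == self.n_max].to_numpy()

    def subset(self, subject_ids) -> "Cohort":
        keep = set(subject_ids)
        return replace(
            self,
            data=self.data[self.data["subject_id"].isin(keep)].reset_index(drop=True),
            baseline=self.baseline.loc[self.baseline.index.isin(keep)],
        )

    def merged(self) -> pd.DataFrame:
        """Long data joined with outcome and baseline covariates."""
        return self.data.merge(
            self.baseline.reset_index().rename(columns={"index": "subject_id"}),
            on="subject_id",
            how="left",
        )

    def model_tv_covariates(self) -> tuple[str, ...]:
        """Time-varying covariates downstream models should adjust for."""
        if self.residualized:
            return tuple(c for c in self.tv_covariates if c not in self.residualized_out)
        return self.tv_covariates

    def model_baseline_covariates(self) -> tuple[str, ...]:
        if self.residualized:
            return tuple(c for c in self.baseline_covariates if c not in self.residualized_out)
        return self.baseline_covariates


# ---------------------------------------------------------------------- #
# IO
# ---------------------------------------------------------------------- #

DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "outcome": "outcome",
    "visit": "visit",
    "time_days": "time_days",
    "exposure": "exposure",
    "tv_covariates": (),
    "baseline_covariates": (),
    "exposure_scale": "raw",
}


def read_cohort_long(path, schema: dict | None = None) -> Cohort:
    """Read a long-format cohort CSV.

    ``schema`` maps canonical names (``subject_id`` ... ``exposure``) to the
    file's column names and declares ``tv_covariates`` / ``baseline_covariates``
    lists plus an ``exposure_scale`` flag.  Rows with missing exposure are
    dropped (and counted in a warning); subjects left with zero visits are
    dropped with a warning.
    """
    sch = dict(DEFAULT_SCHEMA)
    sch.update(schema or {})
    raw = pd.read_csv(path)
    rename = {sch[k]: k for k in ("subject_id", "outcome", "visit", "time_days", "exposure")}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise CohortError(f"input file lacks columns {missing}")
    df = raw.rename(columns=rename)
    tv = tuple(sch["tv_covariates"])
    bl = tuple(sch["baseline_covariates"])

    n_missing = int(df["exposure"].isna().sum())
    if n_missing:
        warnings.warn(f"dropped {n_missing} rows with missing exposure")
        df = df.dropna(subset=["exposure"])
    # outcome must be constant within subject
    per = df.groupby("subject_id")["outcome"].nunique()
    if (per > 1).any():
        bad = per.index[per > 1][0]
        raise CohortError(f"outcome not constant within subject {bad!r}")
    empty = set(raw[sch["subject_id"]].unique()) - set(df["subject_id"].unique())
    if empty:
        warnings.warn(f"dropped {len(empty)} subjects with no remaining visits")

    baseline_cols = ["outcome", *bl]
    baseline = df.groupby("subject_id")[baseline_cols].first()
    data = df[["subject_id", "visit", "time_days", "exposure", *tv]].reset_index(drop=True)
    data["visit"] = data["visit"].astype(int)
    return Cohort(
        data=data,
        baseline=baseline,
        exposure_scale=sch["exposure_scale"],
        tv_covariates=tv,
        baseline_covariates=bl,
    )


def write_cohort_long(cohort: Cohort, path) -> None:
    """Write the cohort back to the canonical long CSV layout."""
    out = cohort.merged()
    cols = ["subject_id", "outcome", "visit", "time_days", "exposure",
            *cohort.tv_covariates, *cohort.baseline_covariates]
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------- #
# Transforms
# ---------------------------------------------------------------------- #

def ln_transform(cohort: Cohort) -> Cohort:
    """Natural-log transform the exposure (raw scale only; idempotence guarded)."""
    if cohort.exposure_scale == "ln":
        raise CohortError("exposure already transformed to the ln scale")
    bad = cohort.data.index[cohort.data["exposure"] <= 0]
    if len(bad):
        raise CohortError(f"cannot log-transform non-positive exposure at rows {list(bad[:10])}")
    data = cohort.data.copy()
    data["exposure"] = np.log(data["exposure"].to_numpy(dtype=float))
    return replace(cohort, data=data, exposure_scale="ln")


def _covariate_matrix(cohort: Cohort, names: list[str]) -> np.ndarray:
    """Assemble per-row covariate values, pulling baseline columns as needed."""
    merged = cohort.merged()
    cols = []
    for name in names:
        if name in cohort.data.columns:
            cols.append(merged[name].to_numpy(dtype=float))
        elif name in cohort.baseline.columns:
            cols.append(merged[name].to_numpy(dtype=float))
        else:
            raise CohortError(f"unknown covariate {name!r}")
    return np.column_stack(cols) if cols else np.empty((len(merged), 0))


def residualize_exposure(cohort: Cohort, covariate_names: list[str]) -> Cohort:
    """Replace ln exposure by residuals of a pooled regression on covariates.

    An empty covariate list is the identity.  The returned cohort is flagged
    ``residualized`` so downstream models omit the removed covariates.
    """
    if cohort.exposure_scale != "ln":
        raise CohortError("residualize_exposure expects an ln-scale cohort")
    if not covariate_names:
        return cohort
    X = _covariate_matrix(cohort, list(covariate_names))
    X = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CohortError(f"rank-deficient design; check collinearity among {covariate_names}")
    y = cohort.data["exposure"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    data = cohort.data.copy()
    data["exposure"] = resid
    return replace(
        cohort,
        data=data,
        residualized=True,
        residualized_out=tuple(covariate_names),
    )


def pivot_wide(cohort: Cohort, require_complete: bool = False):
    """Visit-aligned wide exposure matrix.

    Returns ``(matrix, mask, subject_ids)`` where ``matrix`` is N x n_max with
    NaN at unobserved cells and ``mask`` is True where observed.  With
    ``require_complete`` only fully observed subjects are kept.
    """
    n_max = cohort.n_max
    wide = cohort.data.pivot(index="subject_id", columns="visit", values="exposure")
    wide = wide.reindex(columns=range(1, n_max + 1))
    wide = wide.reindex(cohort.baseline.index)
    mask = wide.notna().to_numpy()
    if require_complete:
        keep = mask.all(axis=1)
        if not keep.any():
            warnings.warn("no complete-case subjects")
        wide = wide.loc[keep]
        mask = mask[keep]
    return wide.to_numpy(dtype=float), mask, wide.index.to_numpy()


# ---------------------------------------------------------------------- #
# Reproducibility diagnostics
# ---------------------------------------------------------------------- #

def _oneway_reml(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML variance components of a random-intercept-only model.

    Model x_ij = mu + b_i + e_ij with b_i ~ N(0, s2b), e ~ N(0, s2e), for an
    unbalanced one-way layout.  Profiles the total variance and optimizes the
    ratio g = s2b/s2e on the log scale.
    """
    uniq, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    sums = np.bincount(inv, weights=values)
    n_tot = len(values)
    ss_tot = float(values @ values)

    def neg2reml(log_g: float) -> float:
        g = np.exp(log_g)
        w = counts / (1.0 + g * counts)          # effective weight per group
        # GLS mean
        mu = float((w / counts * sums).sum() / w.sum())
        # quadratic form r' V^-1 r with V = I + g * block(J)
        r_sums = sums - counts * mu
        quad = (ss_tot - 2 * mu * sums.sum() + n_tot * mu * mu) - g * (r_sums**2 / (1 + g * counts)).sum()
        logdet_v = float(np.log1p(g * counts).sum())
        logdet_xvx = float(np.log(w.sum()))
        s2 = quad / (n_tot - 1)
        return (n_tot - 1) * np.log(max(s2, 1e-300)) + logdet_v + logdet_xvx

    res = minimize_scalar(neg2reml, bounds=(-16, 16), method="bounded")
    g = float(np.exp(res.x))
    w = counts / (1.0 + g * counts)
    mu = float((w / counts * sums).sum() / w.sum())
    r_sums = sums - counts * mu
    quad = (ss_tot - 2 * mu * sums.sum() + n_tot * mu * mu) - g * (r_sums**2 / (1 + g * counts)).sum()
    s2e = float(quad / (n_tot - 1))
    s2b = g * s2e
    return s2b, s2e


def icc(cohort: Cohort, n_boot: int = 500, seed: int = 0, ci_level: float = 0.95) -> IccEstimate:
    """Within-subject reproducibility of the ln exposure.

    Random-intercept model with an intercept as the only fixed effect;
    ICC = between / (between + within).  CI by subject-level bootstrap.
    """
    if cohort.exposure_scale != "ln":
        raise CohortError("icc expects an ln-scale cohort")
    counts = cohort.visits_per_subject()
    if (counts >= 2).sum() < 2:
        raise CohortError("within-subject variance unidentifiable: need >=2 subjects with >=2 visits")
    vals = cohort.data["exposure"].to_numpy(dtype=float)
    grp = cohort.data["subject_id"].to_numpy()
    s2b, s2e = _oneway_reml(vals, grp)
    point = s2b / (s2b + s2e) if (s2b + s2e) > 0 else 0.0

    rng = np.random.default_rng(seed)
    ids = cohort.subject_ids
    by_subject = {sid: np.asarray(idx) for sid, idx in cohort.data.groupby("subject_id").indices.items()}
    boots = []
    for _ in range(n_boot):
        pick = rng.choice(ids, size=len(ids), replace=True)
        rows, labels = [], []
        for k, sid in enumerate(pick):
            idx = by_subject.get(sid)
            if idx is None:
                continue
            rows.append(idx)
            labels.append(np.full(len(idx), k))
        v = vals[np.concatenate(rows)]
        g = np.concatenate(labels)
        # need replicated subjects for identifiability; resampling keeps them whp
        b, e = _oneway_reml(v, g)
        boots.append(b / (b + e) if (b + e) > 0 else 0.0)
    alpha = 1 - ci_level
    if boots:
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    else:
        lo = hi = point
    return IccEstimate(icc=float(point), between_var=float(s2b), within_var=float(s2e),
                       ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


def visit_correlations(cohort: Cohort, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation of ln exposure between visit pairs.

    Each cell uses the subjects observed at both visits (pairwise-complete);
    cells with fewer than ``min_pairs`` common subjects are NaN.
    """
    n_max = cohort.n_max
    wide = cohort.data.pivot(index="subject_id", columns="visit", values="exposure")
    wide = wide.reindex(columns=range(1, n_max + 1))
    out = np.full((n_max, n_max), np.nan)
    for j in range(n_max):
        out[j, j] = 1.0
        for k in range(j + 1, n_max):
            both = wide.iloc[:, [j, k]].dropna()
            if len(both) < min_pairs:
                continue
            r = np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1]
            out[j, k] = out[k, j] = r
    labels = [f"visit_{j}" for j in range(1, n_max + 1)]
    return pd.DataFrame(out, index=labels, columns=labels)
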