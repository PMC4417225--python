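"""Synthetic cohorts with the structure of a pregnancy biomarker study.

The generator emulates a prospective cohort with up to four urine-collection
visits at irregular gestational ages, a right-skewed exposure biomarker whose
ln-scale values follow a random-intercept(/slope) model with a controllable
intraclass correlation, urine specific gravity and time-of-day as time-varying
covariates, roughly 27% cases, and outcome-dependent loss of the final visit
(cases tend to deliver before it).

Outcome mechanisms
------------------
The binary outcome is drawn from a prospective logistic model whose linear
predictor adds ``baseline_logodds`` and one of five effect terms:

``null``    no exposure effect;
``mean``    effect_size x subject mean ln-exposure over scheduled visits;
``window``  effect_size x ln-exposure at one sensitive visit;
``acute``   effect_size x subject max ln-exposure;
``slope``   effect_size x the subject's latent random slope (per week).

Dropout is applied after the outcome is drawn, so the truth record always
refers to the full scheduled exposure history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort

__all__ = ["Scenario", "make_scenario", "simulate_cohort", "truth_check"]

#: visit schedule of the emulated study: (median, min, max) gestational weeks
PHTHALATE_VISITS = (
    (9.79, 4.71, 16.1),
    (17.9, 14.9, 21.9),
    (26.0, 22.9, 29.3),
    (35.1, 33.1, 38.3),
)

#: case fraction of the emulated study (130 cases / 482 subjects)
CASE_FRACTION = 130 / 482


@dataclass(frozen=True)
class Scenario:
    """Generating conditions for one synthetic cohort."""

    n_subjects: int = 480
    visit_schedule: tuple = PHTHALATE_VISITS
    icc_target: float = 0.30
    total_ln_variance: float = 1.0
    slope_sd: float = 0.0           # random slope SD, ln-units per week
    time_trend: float = 0.0         # fixed ln-exposure trend per week
    effect_type: str = "null"
    effect_size: float = 0.0
    window_visit: int = 3
    baseline_logodds: float = float(np.log(CASE_FRACTION / (1 - CASE_FRACTION)))
    case_dropout_prob: float = 0.0
    control_dropout_prob: float = 0.0
    sg_mean: float = 1.015
    sg_sd: float = 0.005
    tod_prob: float = 0.5
    confounding_strength: float = 1.0

    def __post_init__(self):
        meds = [v[0] for v in self.visit_schedule]
        if any(b >= a for a, b in zip(meds[1:], meds[:-1])):
            raise ValueError("visit medians must be strictly increasing")
        if not (0 < self.icc_target < 1):
            raise ValueError("icc_target must lie in (0, 1)")
        for p in (self.case_dropout_prob, self.control_dropout_prob, self.tod_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.total_ln_variance <= 0 or self.slope_sd < 0:
            raise ValueError("variance parameters must be non-negative")
        if self.effect_type not in {"null", "mean", "window", "acute", "slope"}:
            raise ValueError(f"unknown effect_type {self.effect_type!r}")


_PRESETS = {
    "phthalate_like": dict(
        n_subjects=480,
        visit_schedule=PHTHALATE_VISITS,
        icc_target=0.30,
        slope_sd=0.01,
        case_dropout_prob=0.60,
        control_dropout_prob=0.07,
    ),
    "balanced_dense": dict(
        n_subjects=480,
        visit_schedule=tuple((w, w - 1.0, w + 1.0) for w in (8.0, 16.0, 24.0, 32.0)),
        icc_target=0.30,
        slope_sd=0.0,
        case_dropout_prob=0.0,
        control_dropout_prob=0.0,
    ),
    "custom": dict(),
}


def make_scenario(name: str = "phthalate_like", **overrides) -> Scenario:
    """Build a scenario from a named preset plus keyword overrides."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return Scenario(**params)


def simulate_cohort(scenario: Scenario, seed: int) -> tuple[Cohort, pd.DataFrame]:
    """Draw one cohort; deterministic given ``seed``.

    Returns the :class:`Cohort` (raw exposure scale, visit-4 dropout already
    applied) and a per-subject truth record with the latent random effects,
    the realized effect feature, and the outcome linear predictor.
    """
    rng = np.random.default_rng(seed)
    sc = scenario
    N = sc.n_subjects
    n_visits = len(sc.visit_schedule)

    # visit times: uniform within each visit window, sorted to guarantee
    # monotonicity when adjacent windows overlap
    lo = np.array([v[1] for v in sc.visit_schedule])
    hi = np.array([v[2] for v in sc.visit_schedule])
    t_weeks = np.sort(rng.uniform(lo, hi, size=(N, n_visits)), axis=1)
    t_center = t_weeks - t_weeks.mean()

    # variance components at slope_sd = 0: ICC = var_b / (var_b + var_e)
    var_b = sc.icc_target * sc.total_ln_variance
    var_e = (1 - sc.icc_target) * sc.total_ln_variance
    a0 = rng.normal(0.0, np.sqrt(var_b), size=N)
    a1 = rng.normal(0.0, sc.slope_sd, size=N)

    sg = np.clip(rng.normal(sc.sg_mean, sc.sg_sd, size=(N, n_visits)), 1.000, 1.040)
    tod = rng.binomial(1, sc.tod_prob, size=(N, n_visits)).astype(float)
    gamma_sg = 10.0 * sc.confounding_strength   # per SG unit; centered below
    gamma_tod = 0.10 * sc.confounding_strength

    eps = rng.normal(0.0, np.sqrt(var_e), size=(N, n_visits))
    ln_x = (
        sc.time_trend * t_center
        + a0[:, None]
        + a1[:, None] * t_center
        + gamma_sg * (sg - sc.sg_mean)
        + gamma_tod * (tod - sc.tod_prob)
        + eps
    )

    # outcome from the full scheduled history (pre-dropout)
    if sc.effect_type == "null":
        feature = np.zeros(N)
    elif sc.effect_type == "mean":
        feature = ln_x.mean(axis=1)
    elif sc.effect_type == "window":
        feature = ln_x[:, sc.window_visit - 1]
    elif sc.effect_type == "acute":
        feature = ln_x.max(axis=1)
    else:  # slope
        feature = a1
    lin_pred = sc.baseline_logodds + sc.effect_size * feature
    y = rng.binomial(1, expit(lin_pred)).astype(int)

    # outcome-dependent loss of the final visit
    drop_p = np.where(y == 1, sc.case_dropout_prob, sc.control_dropout_prob)
    dropped = rng.uniform(size=N) < drop_p

    # baseline covariates (no outcome effect by default)
    age = rng.normal(32.0, 4.5, size=N)
    bmi = np.clip(rng.normal(26.0, 5.0, size=N), 17.0, 45.0)

    ids = np.arange(1, N + 1)
    rows = {
        "subject_id": np.repeat(ids, n_visits),
        "visit": np.tile(np.arange(1, n_visits + 1), N),
        "time_days": (t_weeks * 7.0).ravel(),
        "exposure": np.exp(ln_x).ravel(),
        "specific_gravity": sg.ravel(),
        "time_of_day": tod.ravel(),
    }
    data = pd.DataFrame(rows)
    last = data["visit"].to_numpy() == n_visits
    keep = ~(last & np.repeat(dropped, n_visits))
    data = data[keep].reset_index(drop=True)

    baseline = pd.DataFrame(
        {"outcome": y, "age": age, "bmi": bmi}, index=pd.Index(ids, name="subject_id")
    )
    cohort = Cohort(
        data=data,
        baseline=baseline,
        exposure_scale="raw",
        tv_covariates=("specific_gravity", "time_of_day"),
        baseline_covariates=("age", "bmi"),
    )
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "a0": a0,
            "a1": a1,
            "effect_feature": feature,
            "linear_predictor": lin_pred,
            "outcome": y,
            "dropped_last_visit": dropped,
        }
    ).set_index("subject_id")
    return cohort, truth


def truth_check(cohort: Cohort, truth: pd.DataFrame, scenario: Scenario) -> dict:
    """Compare realized cohort statistics to scenario targets."""
    from .cohort import icc, ln_transform

    case_fraction = float(cohort.outcomes.mean())
    per_visit_n = cohort.data.groupby("visit").size().to_dict()
    ln_cohort = ln_transform(cohort)
    realized = icc(ln_cohort, n_boot=0)
    return {
        "case_fraction": case_fraction,
        "case_fraction_target": float(expit(scenario.baseline_logodds))
        if scenario.effect_type == "null"
        else None,
        "per_visit_n": per_visit_n,
        "realized_icc": realized.icc,
        "icc_target": scenario.icc_target,
        "n_subjects": cohort.n_subjects,
    }
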