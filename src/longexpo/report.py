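"""Cross-method comparison and the simulation harness.

:func:`compare_methods` runs every requested method on one cohort and
assembles a uniform report (methods that cannot run on the given data report
the reason instead of failing the run).  :func:`simulation_study` measures
operating characteristics — rejection rate of each method's headline test,
and bias/RMSE where the generating scenario defines a target parameter —
over seeded replications of a scenario grid.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import cluster_association, functional_cluster, gmm_cluster
from .cohort import Cohort, ln_transform
from .functional import functional_logistic_model
from .regression import FitError
from .results import MethodResult
from .summary_models import (
    cross_sectional_models,
    max_summary_model,
    mean_summary_model,
    multiple_logistic_model,
)
from .synthetic import Scenario, simulate_cohort
from .trajectory import trajectory_contrast
from .two_stage import two_stage_blup_model, two_stage_cluster_model

__all__ = ["ALL_METHODS", "compare_methods", "simulation_study"]

ALL_METHODS = [
    "multiple", "bayes-multiple", "cross", "mean", "max",
    "twostage", "twostage-cluster", "gamm", "gmm", "fclust", "flr",
]


def _run_method(name: str, cohort: Cohort, opts: dict):
    seed = int(opts.get("seed", 0))
    if name == "multiple":
        return multiple_logistic_model(cohort)
    if name == "bayes-multiple":
        return multiple_logistic_model(cohort, bayes=True)
    if name == "cross":
        return cross_sectional_models(cohort, correction=opts.get("correction", "none"))
    if name == "mean":
        return mean_summary_model(cohort)
    if name == "max":
        return max_summary_model(cohort)
    if name == "twostage":
        return two_stage_blup_model(cohort, slope_policy=opts.get("slope_policy", "auto"),
                                    seed=seed)
    if name == "twostage-cluster":
        res, _ = two_stage_cluster_model(cohort, k=int(opts.get("k", 2)), seed=seed)
        return res
    if name == "gamm":
        fit = trajectory_contrast(cohort, basis_dim=int(opts.get("basis_dim", 8)))
        tests = pd.DataFrame(
            {
                "statistic": [fit.interaction_test["statistic"], np.nan],
                "df": [fit.interaction_test["df"], 1],
                "p": [fit.interaction_test["p"], fit.linear_slope["p"]],
            },
            index=["interaction", "linear_difference_slope"],
        )
        return MethodResult(
            method="trajectory_gamm",
            estimates=pd.DataFrame(columns=["coef", "se", "or", "ci_low", "ci_high", "p"]),
            global_tests=tests,
            n_used=fit.n_used,
            notes=[f"descriptive contrast; EDF of difference = {fit.edf_difference:.2f}; "
                   "risk is not estimated by this method"],
        )
    if name == "gmm":
        model = gmm_cluster(cohort, k_max=int(opts.get("k_max", 3)), seed=seed,
                            k_min=int(opts.get("k_min", 1)))
        return cluster_association(model, cohort)
    if name == "fclust":
        model = functional_cluster(cohort, k=int(opts.get("k", 2)),
                                   residualize=bool(opts.get("residualize", False)),
                                   seed=seed)
        return cluster_association(model, cohort)
    if name == "flr":
        return functional_logistic_model(cohort, L=opts.get("L", 2),
                                         n_basis=int(opts.get("n_basis", 9)))
    raise ValueError(f"unknown method {name!r}")


def compare_methods(cohort: Cohort, config: dict | None = None) -> dict:
    """Run the selected methods on one cohort; never let one failure stop the run."""
    config = config or {}
    methods = config.get("methods", ALL_METHODS)
    opts = config.get("options", {})
    report: dict = {"methods": {}, "config": {"methods": list(methods), "options": opts}}
    timings: dict = {}
    n_ok = 0
    for name in methods:
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = _run_method(name, cohort, dict(opts.get(name, {}), **{
                    k: v for k, v in opts.items() if not isinstance(v, dict)}))
            section = res.to_dict()
            section["status"] = "ok"
            n_ok += 1
        except (FitError, ValueError) as exc:
            section = {"status": "failed", "reason": str(exc)}
        # wall-clock stays out of the report payload so identical runs
        # produce byte-identical JSON
        timings[name] = round(time.perf_counter() - t0, 4)
        report["methods"][name] = section
    report["n_methods_ok"] = n_ok
    report["timings_s"] = timings
    return report


def write_report(report: dict, json_path=None, tsv_path=None) -> None:
    if json_path is not None:
        stable = {k: v for k, v in report.items() if k != "timings_s"}
        with open(json_path, "w") as fh:
            json.dump(stable, fh, indent=2, sort_keys=True)
    if tsv_path is not None:
        rows = []
        for name, sec in report["methods"].items():
            if sec.get("status") != "ok":
                rows.append({"method": name, "term": "", "status": sec.get("reason", "failed")})
                continue
            for term, vals in sec.get("estimates", {}).items():
                rows.append({"method": name, "term": term, "status": "ok", **vals})
            for term, vals in sec.get("global_tests", {}).items():
                rows.append({"method": name, "term": f"test:{term}", "status": "ok", **vals})
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


# ------------------------------------------------------------------ #
# operating characteristics
# ------------------------------------------------------------------ #

def _headline_pvalues(cohort: Cohort, methods, seed: int, options: dict) -> dict:
    """Headline-test p-value (and any target estimate) per requested method."""
    out = {}
    n_max = cohort.n_max
    if "multiple" in methods:
        res = multiple_logistic_model(cohort)
        ps = res.estimates["p"].to_numpy()
        out["multiple_anyvisit_bonferroni"] = {
            "p": float(min(ps.min() * len(ps), 1.0)), "n_used": res.n_used,
            "pervisit_p": ps.tolist()}
    if "cross" in methods:
        res = cross_sectional_models(cohort)
        ps = res.estimates["p"].to_numpy()
        out["cross_gee_equality"] = {"p": float(res.global_tests.loc["gee_equality", "p"]),
                                     "n_used": res.n_used}
        out["cross_anyvisit_bonferroni"] = {
            "p": float(min(ps.min() * len(ps), 1.0)), "n_used": res.n_used,
            "pervisit_p": ps.tolist()}
    if "mean" in methods:
        res = mean_summary_model(cohort)
        row = res.estimates.loc["exposure_mean"]
        out["mean_wald"] = {"p": float(row["p"]), "estimate": float(row["coef"]),
                            "n_used": res.n_used}
    if "max" in methods:
        res = max_summary_model(cohort)
        row = res.estimates.loc["exposure_max"]
        out["max_wald"] = {"p": float(row["p"]), "estimate": float(row["coef"]),
                           "n_used": res.n_used}
    if "twostage" in methods:
        res = two_stage_blup_model(cohort, seed=seed,
                                   slope_policy=options.get("slope_policy", "auto"))
        row = res.estimates.loc["blup_intercept"]
        out["twostage_intercept_wald"] = {"p": float(row["p"]),
                                          "estimate": float(row["coef"]),
                                          "n_used": res.n_used}
        if "blup_slope" in res.estimates.index:
            row = res.estimates.loc["blup_slope"]
            out["twostage_slope_wald"] = {"p": float(row["p"]),
                                          "estimate": float(row["coef"]),
                                          "n_used": res.n_used}
    if "gamm" in methods:
        fit = trajectory_contrast(cohort)
        out["gamm_interaction"] = {"p": float(fit.interaction_test["p"]),
                                   "n_used": fit.n_used,
                                   "edf_difference": float(fit.edf_difference)}
    if "gmm" in methods:
        model = gmm_cluster(cohort, k_max=int(options.get("gmm_k", 2)), seed=seed,
                            k_min=int(options.get("gmm_k", 2)))
        assoc = cluster_association(model, cohort)
        if "cluster_outcome_chi2" in assoc.global_tests.index:
            out["gmm_chi2"] = {"p": float(assoc.global_tests.loc["cluster_outcome_chi2", "p"]),
                               "n_used": assoc.n_used}
    if "fclust" in methods:
        model = functional_cluster(cohort, k=int(options.get("fclust_k", 2)), seed=seed)
        assoc = cluster_association(model, cohort)
        if "cluster_outcome_chi2" in assoc.global_tests.index:
            out["fclust_chi2"] = {"p": float(assoc.global_tests.loc["cluster_outcome_chi2", "p"]),
                                  "n_used": assoc.n_used}
    if "flr" in methods:
        res = functional_logistic_model(cohort, L=int(options.get("flr_L", 2)))
        out["flr_lrt"] = {"p": float(res.global_tests.loc["score_lrt", "p"]),
                          "n_used": res.n_used}
    return out


def simulation_study(scenario_grid: dict[str, Scenario], methods=None, reps: int = 200,
                     alpha: float = 0.05, seed: int = 0, options: dict | None = None,
                     stream_path=None) -> pd.DataFrame:
    """Operating characteristics over seeded replications.

    Returns one row per (scenario, headline test): rejection rate at level
    ``alpha`` with its Monte Carlo standard error, bias and RMSE against the
    scenario's effect size where the test reports a matching estimate, the
    mean analysis n, and the failure fraction.  Per-rep records stream to
    ``stream_path`` (CSV) when given, so long runs can be inspected midway.
    """
    if methods is None:
        methods = ["multiple", "cross", "mean", "max", "twostage", "gamm",
                   "gmm", "fclust", "flr"]
    options = options or {}
    low_reps = reps < 100
    rows = []
    stream_header_written = False
    for s_idx, (label, scenario) in enumerate(scenario_grid.items()):
        recs: dict[str, list] = {}
        failures = 0
        for r in range(reps):
            rep_seed = int(np.random.SeedSequence([seed, s_idx, r]).generate_state(1)[0]
                           % (2**31 - 1))
            cohort, truth = simulate_cohort(scenario, seed=rep_seed)
            lnc = ln_transform(cohort)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pvals = _headline_pvalues(lnc, methods, rep_seed, options)
            except (FitError, np.linalg.LinAlgError):
                failures += 1
                continue
            for test, payload in pvals.items():
                recs.setdefault(test, []).append(payload)
            if stream_path is not None:
                rec = {"scenario": label, "rep": r, "seed": rep_seed,
                       **{f"{t}_p": v["p"] for t, v in pvals.items()}}
                pd.DataFrame([rec]).to_csv(stream_path, mode="a", index=False,
                                           header=not stream_header_written)
                stream_header_written = True
        for test, payloads in recs.items():
            ps = np.array([pl["p"] for pl in payloads])
            rate = float(np.mean(ps < alpha))
            ests = np.array([pl["estimate"] for pl in payloads if "estimate" in pl])
            bias = rmse = np.nan
            if len(ests) and scenario.effect_type != "null":
                target = scenario.effect_size
                bias = float(ests.mean() - target)
                rmse = float(np.sqrt(np.mean((ests - target) ** 2)))
            rows.append({
                "scenario": label,
                "test": test,
                "rejection_rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / len(ps))) if len(ps) else np.nan,
                "bias": bias,
                "rmse": rmse,
                "mean_n_used": float(np.mean([pl["n_used"] for pl in payloads])),
                "reps": len(ps),
                "failed": failures,
                "seed": seed,
                "low_rep_warning": low_reps,
            })
    return pd.DataFrame(rows)
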