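"""Estimation machinery against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import longexpo as le
from longexpo.regression import (
    FitError,
    _logistic_loglik,
    fit_logistic,
    fit_lmm,
    fit_map_logistic,
    fit_pooled_gee,
)
from tests.conftest import build_cohort


def _design(**cols):
    return pd.DataFrame({"intercept": 1.0, **cols})


class TestLogistic:
    def test_intercept_only_balanced(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        fit = fit_logistic(y, _design(dummy=[0.0, 0.0, 1.0, 1.0])[["intercept"]])
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_two_by_two_cross_product_ratio(self):
        # cells: x=1 -> 6 events / 4 non; x=0 -> 3 events / 7 non
        y = np.r_[np.ones(6), np.zeros(4), np.ones(3), np.zeros(7)]
        x = np.r_[np.ones(10), np.zeros(10)]
        fit = fit_logistic(y, _design(x=x))
        assert fit.coefficients["x"] == pytest.approx(np.log(3.5), abs=1e-6)
        # Wald SE closed form: sqrt(sum of reciprocal cell counts)
        assert fit.se["x"] == pytest.approx(np.sqrt(1 / 6 + 1 / 4 + 1 / 3 + 1 / 7),
                                            rel=1e-4)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        X = _design(x1=rng.normal(size=200), x2=rng.binomial(1, 0.4, 200))
        eta = 0.3 * X["x1"] - 0.5 * X["x2"]
        y = rng.binomial(1, expit(eta)).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(ours.coefficients, ref.params, atol=1e-6)
        assert np.allclose(ours.se, ref.bse, atol=1e-6)

    def test_separation_flagged(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        x = np.r_[np.ones(5), np.zeros(5)]
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(y, _design(x=x))
        assert not fit.converged
        assert any("separation" in n for n in fit.notes)

    def test_rank_deficiency_errors(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        X = _design(x=[1.0, 2.0, 3.0, 4.0])
        X["x2"] = 2 * X["x"]
        with pytest.raises(FitError, match="rank"):
            fit_logistic(y, X)

    def test_deviance_monotone_over_irls(self):
        # rerunning with increasing iteration caps traces the IRLS path
        rng = np.random.default_rng(4)
        X = _design(x=rng.normal(size=150))
        y = rng.binomial(1, expit(1.2 * X["x"])).astype(float)
        devs = []
        for cap in range(1, 8):
            fit = fit_logistic(y, X, max_iter=cap)
            devs.append(-2 * fit.loglik)
        assert all(a >= b - 1e-9 for a, b in zip(devs, devs[1:]))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(1)
    n, nv = 40, 3
    Xv = rng.multivariate_normal(np.zeros(nv), 0.5 * np.eye(nv) + 0.5, size=n)
    y = rng.binomial(1, expit(0.4 * Xv[:, 1])).astype(float)
    design = pd.DataFrame(Xv, columns=[f"e{v}" for v in range(1, nv + 1)])
    design.insert(0, "intercept", 1.0)
    return y, design, [f"e{v}" for v in range(1, nv + 1)]


class TestMapLogistic:
    def test_huge_tau2_recovers_mle(self, toy):
        y, X, block = toy
        mle = fit_logistic(y, X)
        mapf = fit_map_logistic(y, X, block, tau2=1e12, rho=0.0)
        assert np.max(np.abs(mapf.coefficients - mle.coefficients)) < 1e-4

    def test_tiny_tau2_kills_exposure_block_only(self, toy):
        y, X, block = toy
        mapf = fit_map_logistic(y, X, block, tau2=1e-12, rho=0.0)
        assert np.max(np.abs(mapf.coefficients[block])) < 1e-4
        # intercept remains free (matches covariate-only MLE)
        mle0 = fit_logistic(y, X[["intercept"]])
        assert mapf.coefficients["intercept"] == pytest.approx(
            mle0.coefficients["intercept"], abs=1e-3)

    def test_matches_generic_optimizer(self, toy):
        y, X, block = toy
        tau2, rho = 0.5, 0.6
        mapf = fit_map_logistic(y, X, block, tau2=tau2, rho=rho)
        idx = np.arange(len(block))
        R = rho ** np.abs(idx[:, None] - idx[None, :])
        Pb = np.linalg.inv(tau2 * R)
        Xm = X.to_numpy()
        cols = [list(X.columns).index(b) for b in block]

        def neg_obj(beta):
            pen = beta[cols] @ Pb @ beta[cols]
            return -(_logistic_loglik(y, Xm @ beta) - 0.5 * pen)

        res = minimize(neg_obj, np.zeros(Xm.shape[1]), method="BFGS",
                       options={"gtol": 1e-10})
        assert np.max(np.abs(mapf.coefficients.to_numpy() - res.x)) < 1e-5

    def test_penalized_norm_shrinkage(self, toy):
        y, X, block = toy
        tau2, rho = 1.0, 0.3
        idx = np.arange(len(block))
        Rinv = np.linalg.inv(rho ** np.abs(idx[:, None] - idx[None, :]))
        mle = fit_logistic(y, X).coefficients[block].to_numpy()
        mapb = fit_map_logistic(y, X, block, tau2=tau2, rho=rho) \
            .coefficients[block].to_numpy()
        assert mapb @ Rinv @ mapb <= mle @ Rinv @ mle + 1e-10

    def test_invalid_prior_params(self, toy):
        y, X, block = toy
        with pytest.raises(FitError):
            fit_map_logistic(y, X, block, tau2=-1.0, rho=0.0)
        with pytest.raises(FitError):
            fit_map_logistic(y, X, block, tau2=1.0, rho=1.0)


def _random_intercept_cohort(N, n, s2b, s2e, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(N):
        b = rng.normal(0, np.sqrt(s2b))
        for j in range(n):
            rows.append((i + 1, j + 1, 50.0 + 30 * j,
                         float(b + rng.normal(0, np.sqrt(s2e)))))
    return build_cohort(rows, {i + 1: 0 for i in range(N)}, scale="ln")


class TestLmm:
    def test_noiseless_subject_constants(self):
        c = _random_intercept_cohort(25, 3, 1.0, 1e-14, seed=2)
        fit = fit_lmm(c, random_slope=False, fixed_covariates=[])
        assert fit.resid_var < 1e-6
        x = c.data.groupby("subject_id")["exposure"].mean()
        dev = x - x.mean()
        # near-zero noise means essentially no shrinkage
        assert np.max(np.abs(fit.blups["intercept"] - dev)) < 1e-4

    def test_balanced_shrinkage_closed_form(self):
        c = _random_intercept_cohort(60, 4, 1.0, 1.0, seed=3)
        fit = fit_lmm(c, random_slope=False, fixed_covariates=[])
        xbar = c.data.groupby("subject_id")["exposure"].mean()
        # GLS grand mean under a balanced design equals the mean of means
        shrink = fit.var_intercept / (fit.var_intercept + fit.resid_var / 4)
        expected = shrink * (xbar - xbar.mean())
        assert np.max(np.abs(fit.blups["intercept"] - expected)) < 1e-8

    def test_reml_beats_grid(self):
        c = _random_intercept_cohort(6, 3, 0.8, 0.5, seed=4)
        fit = fit_lmm(c, random_slope=False, fixed_covariates=[])
        vals = c.data["exposure"].to_numpy()
        groups = c.data["subject_id"].to_numpy()

        def neg2reml(s2b, s2e):
            uniq = np.unique(groups)
            V_list, r = [], vals.astype(float)
            # direct dense evaluation for the oracle
            n = len(vals)
            V = np.zeros((n, n))
            for u in uniq:
                m = groups == u
                V[np.ix_(m, m)] += s2b
            V += s2e * np.eye(n)
            X = np.ones((n, 1))
            Vi = np.linalg.inv(V)
            XtVi = X.T @ Vi
            beta = np.linalg.solve(XtVi @ X, XtVi @ vals)
            resid = vals - X @ beta
            _, ld = np.linalg.slogdet(V)
            _, ldx = np.linalg.slogdet(XtVi @ X)
            return ld + ldx + resid @ Vi @ resid

        opt = neg2reml(fit.var_intercept, fit.resid_var)
        for s2b in np.linspace(0.05, 3.0, 20):
            for s2e in np.linspace(0.05, 3.0, 20):
                assert opt <= neg2reml(s2b, s2e) + 1e-6

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        rows = []
        for i in range(120):
            a0 = rng.normal(0, 1.0)
            a1 = rng.normal(0, 0.15)
            for j in range(4):
                t = 50.0 + 30 * j + rng.uniform(-5, 5)
                tw = (t - 95.0) / 7
                rows.append((i + 1, j + 1, t, float(1.0 + a0 + a1 * tw
                                                    + rng.normal(0, 0.6))))
        c = build_cohort(rows, {i + 1: 0 for i in range(120)}, scale="ln")
        fit = fit_lmm(c, random_slope=True, fixed_covariates=[])
        d = c.data.copy()
        d["tw"] = (d["time_days"] - d["time_days"].mean()) / 7.0
        ref = smf.mixedlm("exposure ~ tw", d, groups=d["subject_id"],
                          re_formula="~tw").fit(reml=True)
        assert fit.var_intercept == pytest.approx(ref.cov_re.iloc[0, 0], rel=0.02)
        assert fit.var_slope == pytest.approx(ref.cov_re.iloc[1, 1], rel=0.05)
        assert fit.resid_var == pytest.approx(ref.scale, rel=0.02)
        assert np.allclose(fit.fixed_effects.to_numpy(), ref.fe_params.to_numpy(),
                           atol=1e-3)

    def test_blups_center_near_zero(self, phthalate_ln_cohort):
        cohort, _, _ = phthalate_ln_cohort
        fit = fit_lmm(cohort, random_slope=False)
        w = cohort.visits_per_subject().loc[fit.blups.index].to_numpy()
        weighted = np.average(fit.blups["intercept"], weights=w)
        assert abs(weighted) < 0.02

    def test_random_slope_needs_replication(self):
        c = build_cohort([(1, 1, 70.0, 1.0), (2, 1, 80.0, 2.0)], {1: 0, 2: 1},
                         scale="ln")
        with pytest.raises(FitError):
            fit_lmm(c, random_slope=True, fixed_covariates=[])


class TestPooledGee:
    def test_visit_estimates_equal_cross_sectional_mles(self, phthalate_ln_cohort):
        cohort, _, _ = phthalate_ln_cohort
        gee = fit_pooled_gee(cohort)
        cs = le.cross_sectional_models(cohort)
        assert np.max(np.abs(gee.visit_betas.to_numpy()
                             - cs.estimates["coef"].to_numpy())) < 1e-6

    def test_single_visit_degenerate(self):
        rng = np.random.default_rng(9)
        rows = [(i + 1, 1, 70.0, float(rng.normal())) for i in range(80)]
        y = {i + 1: int(rng.binomial(1, 0.3)) for i in range(80)}
        c = build_cohort(rows, y, scale="ln")
        gee = fit_pooled_gee(c, tv_covariates=[], baseline_covariates=[])
        assert gee.equality_df == 0
        assert np.isnan(gee.equality_p)
        single = fit_logistic(np.array([y[i + 1] for i in range(80)], dtype=float),
                              _design(x=[r[3] for r in rows]))
        assert gee.visit_betas.iloc[0] == pytest.approx(single.coefficients["x"],
                                                        abs=1e-8)

    def test_sandwich_close_to_model_based_when_independent(self):
        rng = np.random.default_rng(10)
        rows = [(i + 1, 1, 70.0, float(rng.normal())) for i in range(400)]
        y = {i + 1: int(rng.binomial(1, 0.3)) for i in range(400)}
        c = build_cohort(rows, y, scale="ln")
        gee = fit_pooled_gee(c, tv_covariates=[], baseline_covariates=[])
        mle = fit_logistic(np.array([y[i + 1] for i in range(400)], dtype=float),
                           _design(x=[r[3] for r in rows]))
        ratio = gee.visit_se.iloc[0] / mle.se["x"]
        assert 0.8 < ratio < 1.25

    def test_equality_test_level(self):
        # equal true coefficients across visits: chi-square test well calibrated
        sc = le.make_scenario("balanced_dense", n_subjects=400,
                              effect_type="mean", effect_size=0.4)
        rej = 0
        reps = 60
        for r in range(reps):
            cohort, _ = le.simulate_cohort(sc, seed=3000 + r)
            gee = fit_pooled_gee(le.ln_transform(cohort))
            rej += gee.equality_p < 0.05
        assert rej / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
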