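"""Cohort data model: IO round trips, transforms, ICC and correlations."""

import numpy as np
import pandas as pd
import pytest

import longexpo as le
from longexpo.cohort import Cohort, CohortError
from tests.conftest import build_cohort


class TestIO:
    def test_read_toy_csv_visit_counts(self, tmp_path):
        path = tmp_path / "toy.csv"
        pd.DataFrame(
            {
                "subject_id": [1, 1, 2, 2, 2, 3],
                "outcome": [1, 1, 0, 0, 0, 1],
                "visit": [1, 2, 1, 2, 3, 1],
                "time_days": [70, 140, 65, 130, 200, 80],
                "exposure": [1.0, 2.0, 0.5, 1.5, 2.5, 3.0],
            }
        ).to_csv(path, index=False)
        cohort = le.read_cohort_long(path)
        assert cohort.visits_per_subject().tolist() == [2, 3, 1]
        assert cohort.n_max == 3

    def test_outcome_flip_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "subject_id": [1, 1],
                "outcome": [1, 0],
                "visit": [1, 2],
                "time_days": [70, 140],
                "exposure": [1.0, 2.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(CohortError, match="outcome not constant"):
            le.read_cohort_long(path)

    def test_round_trip(self, tmp_path, phthalate_ln_cohort):
        cohort, _, _ = phthalate_ln_cohort
        path = tmp_path / "cohort.csv"
        le.write_cohort_long(cohort, path)
        schema = {
            "tv_covariates": list(cohort.tv_covariates),
            "baseline_covariates": list(cohort.baseline_covariates),
            "exposure_scale": "ln",
        }
        back = le.read_cohort_long(path, schema)
        pd.testing.assert_frame_equal(
            back.data.sort_values(["subject_id", "visit"]).reset_index(drop=True),
            cohort.data.sort_values(["subject_id", "visit"]).reset_index(drop=True),
            check_dtype=False,
        )
        assert back.outcomes.tolist() == cohort.outcomes.tolist()

    def test_duplicate_visit_rejected(self):
        with pytest.raises(CohortError, match="duplicate"):
            build_cohort([(1, 1, 70.0, 1.0), (1, 1, 80.0, 2.0)], {1: 1}, scale="raw")

    def test_missing_exposure_rows_dropped_with_count(self, tmp_path):
        path = tmp_path / "na.csv"
        pd.DataFrame(
            {
                "subject_id": [1, 1, 2],
                "outcome": [1, 1, 0],
                "visit": [1, 2, 1],
                "time_days": [70, 140, 80],
                "exposure": [1.0, np.nan, 2.0],
            }
        ).to_csv(path, index=False)
        with pytest.warns(UserWarning, match="1 rows"):
            cohort = le.read_cohort_long(path)
        assert len(cohort.data) == 2


class TestTransforms:
    def test_ln_closed_form(self):
        c = build_cohort(
            [(1, 1, 10.0, 1.0), (1, 2, 20.0, np.e), (1, 3, 30.0, np.e**2)],
            {1: 0}, scale="raw",
        )
        out = le.ln_transform(c)
        assert np.allclose(out.data["exposure"], [0.0, 1.0, 2.0])
        assert out.exposure_scale == "ln"

    def test_ln_idempotence_guard(self, phthalate_ln_cohort):
        cohort, _, _ = phthalate_ln_cohort
        with pytest.raises(CohortError, match="already"):
            le.ln_transform(cohort)

    def test_ln_rejects_nonpositive(self):
        c = build_cohort([(1, 1, 10.0, 1.0)], {1: 0}, scale="raw")
        c.data.loc[0, "exposure"] = 0.0
        with pytest.raises(CohortError):
            le.ln_transform(c)

    def test_residualize_empty_is_identity(self, phthalate_ln_cohort):
        cohort, _, _ = phthalate_ln_cohort
        out = le.residualize_exposure(cohort, [])
        assert out is cohort

    def test_residualize_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        sg = rng.uniform(1.0, 1.04, 30)
        rows = [(i + 1, 1, 70.0, 2.0 + 5.0 * sg[i], sg[i]) for i in range(30)]
        c = build_cohort(rows, {i + 1: 0 for i in range(30)},
                         tv=("specific_gravity",), scale="ln")
        out = le.residualize_exposure(c, ["specific_gravity"])
        assert np.max(np.abs(out.data["exposure"])) < 1e-10

    def test_residualize_orthogonality(self, phthalate_ln_cohort):
        cohort, _, _ = phthalate_ln_cohort
        out = le.residualize_exposure(cohort, ["specific_gravity", "time_of_day"])
        r = out.data["exposure"].to_numpy()
        for cov in ("specific_gravity", "time_of_day"):
            z = out.data[cov].to_numpy()
            rho = np.corrcoef(r, z)[0, 1]
            assert abs(rho) < 1e-8
        assert out.residualized
        assert out.model_tv_covariates() == ()

    def test_residualize_rank_deficient(self, phthalate_ln_cohort):
        cohort, _, _ = phthalate_ln_cohort
        dup = cohort.data.copy()
        dup["sg_copy"] = dup["specific_gravity"]
        from dataclasses import replace
        c2 = replace(cohort, data=dup,
                     tv_covariates=(*cohort.tv_covariates, "sg_copy"))
        with pytest.raises(CohortError, match="rank"):
            le.residualize_exposure(c2, ["specific_gravity", "sg_copy"])


class TestPivot:
    def test_counts(self, toy_cohort):
        lnc = le.ln_transform(toy_cohort)
        full, mask, ids = le.pivot_wide(lnc, require_complete=False)
        assert full.shape == (3, 3)
        assert int((~mask).sum()) == 3
        comp, _, comp_ids = le.pivot_wide(lnc, require_complete=True)
        assert comp.shape == (1, 3)
        assert comp_ids.tolist() == [2]

    def test_balanced_equal_under_both_flags(self, balanced_ln_cohort):
        cohort, _, _ = balanced_ln_cohort
        a, _, _ = le.pivot_wide(cohort, require_complete=False)
        b, _, _ = le.pivot_wide(cohort, require_complete=True)
        assert np.array_equal(a, b)

    def test_complete_never_exceeds_full(self, phthalate_ln_cohort):
        cohort, _, _ = phthalate_ln_cohort
        a, _, _ = le.pivot_wide(cohort, require_complete=False)
        b, _, _ = le.pivot_wide(cohort, require_complete=True)
        assert b.shape[0] <= a.shape[0]


class TestIcc:
    def test_constant_within_subject_gives_one(self):
        rows = []
        for i in range(20):
            for j in range(3):
                rows.append((i + 1, j + 1, 50.0 + 30 * j, float(i)))
        c = build_cohort(rows, {i + 1: 0 for i in range(20)}, scale="ln")
        est = le.icc(c, n_boot=10, seed=0)
        assert est.icc > 1 - 1e-6

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(500):
            for j in range(4):
                rows.append((i + 1, j + 1, 50.0 + 30 * j, float(rng.normal())))
        c = build_cohort(rows, {i + 1: 0 for i in range(500)}, scale="ln")
        est = le.icc(c, n_boot=0)
        assert est.icc < 0.05

    def test_half_and_half_variance(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(500):
            b = rng.normal()
            for j in range(4):
                rows.append((i + 1, j + 1, 50.0 + 30 * j, float(b + rng.normal())))
        c = build_cohort(rows, {i + 1: 0 for i in range(500)}, scale="ln")
        est = le.icc(c, n_boot=50, seed=1)
        assert est.icc == pytest.approx(0.5, abs=0.05)
        assert est.ci_low <= est.icc <= est.ci_high

    def test_shift_invariance(self, phthalate_ln_cohort):
        from dataclasses import replace
        cohort, _, _ = phthalate_ln_cohort
        base = le.icc(cohort, n_boot=0)
        d = cohort.data.copy()
        d["exposure"] = d["exposure"] + 7.5
        shifted = le.icc(replace(cohort, data=d), n_boot=0)
        assert shifted.icc == pytest.approx(base.icc, abs=1e-6)

    def test_single_visit_only_errors(self):
        c = build_cohort([(1, 1, 70.0, 1.0), (2, 1, 80.0, 2.0)], {1: 0, 2: 1},
                         scale="ln")
        with pytest.raises(CohortError, match="unidentifiable"):
            le.icc(c)


class TestVisitCorrelations:
    def test_identical_across_visits(self):
        rows = []
        for i in range(30):
            for j in range(3):
                rows.append((i + 1, j + 1, 50.0 + 30 * j, float(i % 7)))
        c = build_cohort(rows, {i + 1: 0 for i in range(30)}, scale="ln")
        corr = le.visit_correlations(c)
        off = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(500):
            for j in range(4):
                rows.append((i + 1, j + 1, 50.0 + 30 * j, float(rng.normal())))
        c = build_cohort(rows, {i + 1: 0 for i in range(500)}, scale="ln")
        corr = le.visit_correlations(c).to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_exchangeable_structure_matches_icc(self):
        # pairwise correlation of an exchangeable process equals its ICC
        scenario = le.make_scenario("phthalate_like", icc_target=0.57,
                                    slope_sd=0.0, case_dropout_prob=0.0,
                                    control_dropout_prob=0.0,
                                    confounding_strength=0.0)
        cohort, _ = le.simulate_cohort(scenario, seed=12)
        corr = le.visit_correlations(le.ln_transform(cohort)).to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.mean(off) == pytest.approx(0.57, abs=0.06)

    def test_sparse_pair_marked_unavailable(self, toy_cohort):
        corr = le.visit_correlations(le.ln_transform(toy_cohort))
        assert np.isnan(corr.iloc[0, 2])
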