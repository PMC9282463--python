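"""Selection cascade: VIF, candidates, CV, AIC comparison, retention."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cpuestd.gam import ModelSpec, SmoothTerm
from cpuestd.selection import (CVResult, candidate_models,
                               compare_models_aic, final_model,
                               repeated_kfold_cv, retention_rule, rmse,
                               rmse_compare, vif_backward)

#: the printed per-term significance counts of the full model's first
#: cross-validation (biomass response), used for the retention replay
PUBLISHED_BIOMASS_COUNTS = {
    "lat": 99, "depth": 100, "BT": 18, "Oxy": 96, "Sal": 98, "week": 0,
    "todsunset": 100, "fisheryL": 95, "fisheryN": 89,
    "year:fisheryY": 100, "year:fisheryL": 0, "year:fisheryN": 100,
}


class TestVIF:
    def test_near_duplicate_longitude_removed(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(42.7, 43.6, 200)
        d = pd.DataFrame({
            "lat": lat,
            "lon": lat + rng.normal(0, 0.01, 200),   # lon ~ lat + noise
            "depth": rng.uniform(100, 270, 200),
            "Oxy": rng.uniform(60, 95, 200),
        })
        kept, trace = vif_backward(d, ["lat", "lon", "depth", "Oxy"])
        assert "lon" not in kept or "lat" not in kept
        final_vifs = trace[-1]
        assert all(v < 3.0 for v in final_vifs.values())

    def test_orthogonal_covariates_untouched(self):
        rng = np.random.default_rng(1)
        d = pd.DataFrame(rng.standard_normal((300, 4)),
                         columns=list("abcd"))
        kept, trace = vif_backward(d, list("abcd"))
        assert kept == list("abcd")
        assert all(v == pytest.approx(1.0, abs=0.1)
                   for v in trace[0].values())

    def test_vif_equals_inverse_one_minus_r2_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((150, 3))
        X[:, 2] += 0.8 * X[:, 0]
        d = pd.DataFrame(X, columns=["a", "b", "c"])
        _, trace = vif_backward(d, ["a", "b", "c"], threshold=1e9)
        for col in ("a", "b", "c"):
            others = [c for c in ("a", "b", "c") if c != col]
            ols = sm.OLS(d[col], sm.add_constant(d[others])).fit()
            assert trace[0][col] == pytest.approx(
                1.0 / (1.0 - ols.rsquared), rel=1e-8)

    def test_perfect_collinearity_dropped_deterministically(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(100)
        d = pd.DataFrame({"a": a, "b": a.copy(),
                          "c": rng.standard_normal(100)})
        kept, _ = vif_backward(d, ["a", "b", "c"])
        assert kept == ["b", "c"]  # alphabetical tie-break drops 'a'

    def test_preconditions(self):
        d = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            vif_backward(d, ["a"])
        with pytest.raises(ValueError):
            vif_backward(d.head(2), ["a", "b"])


class TestCandidateModels:
    def test_model_without_environment_and_management(self):
        spec = candidate_models("biomass_index")["modNOEM"]
        assert {s.covariate for s in spec.smooths} == {"lat", "depth",
                                                       "week", "year"}
        assert all(s.by is None for s in spec.smooths)
        assert spec.factors == ("tod",)

    def test_full_model_has_interaction_and_intercept(self):
        spec = candidate_models("biomass_index")["modINITIAL"]
        by = [s for s in spec.smooths if s.by == "fishery"]
        assert len(by) == 1 and by[0].covariate == "year"
        assert "fishery" in spec.factors

    def test_all_candidates_share_response_family_link(self):
        cands = candidate_models("density_index")
        assert len(cands) == 4
        for spec in cands.values():
            assert spec.response == "density_index"
            assert (spec.family, spec.link) == ("gamma", "log")
            assert all(s.k <= 6 for s in spec.smooths)

    def test_final_model_drops_bt_and_week(self):
        spec = final_model("biomass_index")
        covs = {s.covariate for s in spec.smooths}
        assert "BT" not in covs and "week" not in covs
        assert covs == {"lat", "depth", "Oxy", "Sal", "year"}


@pytest.fixture(scope="module")
def cv(survey_dataset):
    spec = ModelSpec("biomass_index", smooths=(SmoothTerm("depth"),),
                     factors=("tod",))
    return repeated_kfold_cv(spec, survey_dataset["filtered"],
                             k=10, repeats=10, seed=42)


class TestRepeatedKFoldCV:

    def test_hundred_aic_values(self, cv):
        assert len(cv.aic) == 100
        assert cv.n_fits == 100
        assert np.isfinite(cv.aic).all()
        assert len(cv.rmse) == 100

    def test_pvalue_counts_bounded(self, cv):
        for term, c in cv.pvalue_counts.items():
            assert 0 <= c <= 100

    def test_partitions_disjoint_and_exhaustive(self, survey_dataset):
        from cpuestd.selection import _partition
        rng = np.random.default_rng(5)
        n = len(survey_dataset["filtered"])
        folds = _partition(n, 10, rng)
        allidx = np.concatenate(folds)
        assert len(allidx) == n
        assert len(np.unique(allidx)) == n

    def test_deterministic_under_seed(self, survey_dataset):
        spec = ModelSpec("biomass_index", smooths=(SmoothTerm("depth"),),
                         factors=("tod",))
        a = repeated_kfold_cv(spec, survey_dataset["filtered"], k=5,
                              repeats=2, seed=9)
        b = repeated_kfold_cv(spec, survey_dataset["filtered"], k=5,
                              repeats=2, seed=9)
        assert np.array_equal(a.aic, b.aic)

    def test_sparse_factor_level_rejected(self, survey_dataset):
        filt = survey_dataset["filtered"]
        few = pd.concat([filt[filt["fishery"] == "Y"].head(15),
                         filt[filt["fishery"] == "L"].head(12),
                         filt[filt["fishery"] == "N"].head(3)])
        spec = ModelSpec("biomass_index", factors=("fishery",))
        with pytest.raises(ValueError, match="fewer than"):
            repeated_kfold_cv(spec, few, k=10, repeats=1)


def _cv_from_aic(name, aic):
    return CVResult(candidate=name, aic=np.asarray(aic, dtype=float),
                    n_fits=len(aic))


class TestCompareModelsAIC:
    def test_identical_vectors_select_simplest(self):
        aic = np.full(40, 100.0)
        cvs = {n: _cv_from_aic(n, aic)
               for n in ("modINITIAL", "modNOEM", "modNOE", "modNOM")}
        comp = compare_models_aic(cvs)
        assert comp.selected == "modNOEM"

    def test_clear_separation_selects_lowest_mean(self):
        rng = np.random.default_rng(7)
        means = {"modINITIAL": 100.0, "modNOE": 140.0, "modNOM": 180.0,
                 "modNOEM": 220.0}   # 10 pooled SDs apart (sd=4)
        cvs = {n: _cv_from_aic(n, rng.normal(m, 4.0, 50))
               for n, m in means.items()}
        comp = compare_models_aic(cvs)
        assert comp.selected == "modINITIAL"
        assert comp.homoscedastic
        assert comp.anova_p < 0.05
        assert comp.pairwise["reject"].all()

    def test_unequal_lengths_rejected(self):
        cvs = {"modINITIAL": _cv_from_aic("modINITIAL", np.ones(10)),
               "modNOEM": _cv_from_aic("modNOEM", np.ones(12))}
        with pytest.raises(ValueError):
            compare_models_aic(cvs)

    def test_heteroscedastic_falls_back_to_welch(self):
        rng = np.random.default_rng(8)
        cvs = {"modINITIAL": _cv_from_aic("modINITIAL",
                                          rng.normal(100, 0.5, 60)),
               "modNOEM": _cv_from_aic("modNOEM", rng.normal(160, 30, 60)),
               "modNOE": _cv_from_aic("modNOE", rng.normal(130, 1.0, 60)),
               "modNOM": _cv_from_aic("modNOM", rng.normal(145, 15, 60))}
        comp = compare_models_aic(cvs)
        assert not comp.homoscedastic
        assert comp.selected == "modINITIAL"


class TestRetentionRule:
    def _cv(self, counts, total=100):
        return CVResult(candidate="modINITIAL", aic=np.zeros(total),
                        pvalue_counts=dict(counts), n_fits=total)

    def test_printed_counts_reproduce_final_term_set(self):
        """Feeding the published significance counts through the rule
        yields exactly the final model's terms: BT and week dropped, the
        full year-by-fishery interaction and both factors kept."""
        retained = retention_rule(self._cv(PUBLISHED_BIOMASS_COUNTS),
                                  threshold=0.80)
        assert retained == {
            "lat", "depth", "Oxy", "Sal", "todsunset",
            "fisheryL", "fisheryN",
            "year:fisheryY", "year:fisheryL", "year:fisheryN",
        }

    def test_all_significant_all_retained(self):
        counts = {t: 100 for t in PUBLISHED_BIOMASS_COUNTS}
        retained = retention_rule(self._cv(counts))
        assert retained == set(PUBLISHED_BIOMASS_COUNTS)

    def test_boundary_80_retained_79_dropped(self):
        retained = retention_rule(self._cv({"Oxy": 80, "Sal": 79}))
        assert "Oxy" in retained and "Sal" not in retained

    def test_interaction_any_level_rule(self):
        counts = {"year:fisheryY": 100, "year:fisheryL": 0,
                  "year:fisheryN": 0, "fisheryL": 10, "fisheryN": 5}
        retained = retention_rule(self._cv(counts))
        # one passing level keeps every level and the parent intercepts
        assert {"year:fisheryY", "year:fisheryL", "year:fisheryN",
                "fisheryL", "fisheryN"} <= retained

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(11)
        base = {t: int(rng.integers(0, 101))
                for t in PUBLISHED_BIOMASS_COUNTS}
        r0 = retention_rule(self._cv(base))
        for t in base:
            bumped = dict(base)
            bumped[t] = min(100, base[t] + 20)
            r1 = retention_rule(self._cv(bumped))
            assert r0 - {t} <= r1  # raising a count never removes others


class TestRMSE:
    def test_three_residual_toy(self):
        assert rmse([1.0, 2.0, 2.0]) == pytest.approx(np.sqrt(3.0))

    def test_identical_specs_identical_vectors(self, survey_dataset):
        spec = ModelSpec("biomass_index", smooths=(SmoothTerm("depth"),),
                         factors=("tod",))
        out = rmse_compare(spec, spec, survey_dataset["filtered"],
                           k=5, repeats=1, seed=3)
        assert np.array_equal(out["rmse_a"], out["rmse_b"])


class TestCascadeRecovery:
    def test_cascade_recovers_generating_term_set(self, geometry,
                                                         timeline, effects):
        """Generating data from the final-model structure (no BT or week
        effects) and running the full-model CV retention recovers exactly
        the final term set in at least 80 % of 20 replicate datasets."""
        from cpuestd.cpue import compute_indices, filter_records
        from cpuestd.simulate import SurveyPlan, simulate_survey_series

        final_terms = {"lat", "depth", "Oxy", "Sal", "todsunset",
                       "fisheryL", "fisheryN", "year:fisheryY",
                       "year:fisheryL", "year:fisheryN"}
        spec = candidate_models("biomass_index")["modINITIAL"]
        hits = 0
        for seed in range(20):
            hauls, _ = simulate_survey_series(geometry, timeline, effects,
                                              SurveyPlan(), seed=seed)
            filt, _ = filter_records(compute_indices(hauls))
            cv = repeated_kfold_cv(spec, filt, k=10, repeats=10,
                                   seed=seed + 1000)
            hits += retention_rule(cv, threshold=0.80) == final_terms
        assert hits >= 16
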