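import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from ecoloc.simulate import SurvivalConfig, draw_survival
from ecoloc.survival import (
    REFERENCE_CUTOFFS,
    apply_administrative_censoring,
    bootstrap_significance,
    candidate_percentiles,
    cox_fit,
    dichotomize,
    km_estimate,
    logrank_by_group,
    logrank_test,
    optimal_cutoff_search,
    subtype_stratified_analysis,
    tissue_subsampling_robustness,
)
from ecoloc.tessellation import QuadratCounts


class TestKaplanMeier:
    def test_no_censoring_two_events(self):
        km = km_estimate([12.0, 24.0], [1, 1])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_all_censored_curve_is_flat_one(self):
        km = km_estimate([10.0, 20.0, 30.0], [0, 0, 0])
        assert km.survival_at(0.0) == 1.0
        assert km.survival_at(100.0) == 1.0
        assert km.total_events == 0

    def test_hand_computed_product_limit(self):
        # events at 5, 12, 25, 30; censored at 8+ and 20+
        km = km_estimate([5, 8, 12, 20, 25, 30], [1, 0, 1, 0, 1, 1])
        np.testing.assert_allclose(km.survival, [5 / 6, 5 / 8, 5 / 16, 0.0])
        np.testing.assert_array_equal(km.at_risk, [6, 4, 2, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_curve_non_increasing_property(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = rng.integers(3, 40)
            km = km_estimate(
                rng.exponential(50, n), rng.integers(0, 2, n)
            )
            assert km.survival_at(0) == 1.0 or len(km.times) == 0
            assert np.all(np.diff(km.survival) <= 1e-12)


class TestLogRank:
    def test_hand_computed_statistic(self):
        # A events at 1, 2; B events at 3, 4: chi2 = (2 - 5/6)^2 / (1/4 + 2/9)
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx((2 - 5 / 6) ** 2 / (1 / 4 + 2 / 9))
        assert p == pytest.approx(0.0896, abs=1e-3)

    def test_identical_groups_are_null(self):
        chi2, p = logrank_test([5, 10, 15], [1, 0, 1], [5, 10, 15], [1, 0, 1])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(40, 30), rng.exponential(60, 25)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
        assert logrank_test(ta, ea, tb, eb)[0] == pytest.approx(
            logrank_test(tb, eb, ta, ea)[0]
        )

    def test_matches_lifelines(self):
        rng = np.random.default_rng(8)
        ta, tb = rng.exponential(40, 60), rng.exponential(70, 50)
        ea, eb = rng.integers(0, 2, 60), rng.integers(0, 2, 50)
        chi2, p = logrank_test(ta, ea, tb, eb)
        ref = lifelines_logrank(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_is_missing(self):
        with pytest.warns(UserWarning):
            chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert np.isnan(chi2) and np.isnan(p)


class TestCutoffSearch:
    def test_grid_has_41_candidates(self):
        assert len(candidate_percentiles(20, 80, 1.5)) == 41

    def test_result_table_covers_grid(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, 200)
        t, e = draw_survival(rng, np.log(0.3) * (scores > 0.5), SurvivalConfig(scale=150))
        res = optimal_cutoff_search(scores, t, e)
        assert len(res.candidates) == 41
        valid = res.candidates.dropna(subset=["p"])
        assert res.candidates.loc[valid["p"].idxmin(), "cutoff"] == res.chosen_cutoff

    def test_invariant_to_patient_ordering(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 150)
        t, e = draw_survival(rng, np.log(0.3) * (scores > 0.4), SurvivalConfig(scale=150))
        res = optimal_cutoff_search(scores, t, e)
        perm = rng.permutation(150)
        res_p = optimal_cutoff_search(scores[perm], t[perm], e[perm])
        assert res.chosen_cutoff == pytest.approx(res_p.chosen_cutoff)
        assert res.chosen_percentile == res_p.chosen_percentile

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff_search([1.0] * 10, np.arange(1, 11), np.ones(10, int))

    def test_dichotomization_ties_go_low(self):
        assert not dichotomize([0.5], 0.5)[0]
        assert dichotomize([0.5001], 0.5)[0]

    def test_reference_cutoffs_available(self):
        # the frozen thresholds shipped for scoring comparable data
        assert REFERENCE_CUTOFFS["all"]["morisita"] == 0.6940734
        assert REFERENCE_CUTOFFS["all"]["pearson"] == 0.4884236
        assert REFERENCE_CUTOFFS["LumA"]["morisita"] == 0.639985
        assert REFERENCE_CUTOFFS["LumB"]["morisita"] == 0.7439517
        assert REFERENCE_CUTOFFS["Basal"]["morisita"] == 0.699701
        assert REFERENCE_CUTOFFS["HER2"]["morisita"] == 0.7106531


class TestCox:
    def test_null_binary_covariate(self):
        rng = np.random.default_rng(14)
        x = (rng.uniform(size=400) < 0.5).astype(float)
        t, e = draw_survival(rng, np.zeros(400), SurvivalConfig(scale=200))
        res = cox_fit(pd.DataFrame({"time": t, "event": e, "x": x}), covariates=["x"])
        lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
        assert lo < 1 < hi
        assert res.hr("x") == pytest.approx(1.0, abs=0.5)

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(21)
        n = 1000
        x = (rng.uniform(size=n) < 0.5).astype(float)
        t, e = draw_survival(rng, np.log(0.4) * x, SurvivalConfig(scale=200))
        res = cox_fit(pd.DataFrame({"time": t, "event": e, "x": x}), covariates=["x"])
        coef = float(res.table.loc["x", "coef"])
        se = (np.log(res.table.loc["x", "ci_high"]) - np.log(res.table.loc["x", "ci_low"])) / (
            2 * 1.959964
        )
        assert abs(coef - np.log(0.4)) < 3 * se
        assert res.table.loc["x", "hr"] == pytest.approx(np.exp(coef))

    def test_separation_is_flagged_not_silent(self):
        # a covariate that perfectly orders survival cannot converge sensibly
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        x = (t > 10).astype(float)
        res = cox_fit(pd.DataFrame({"time": t, "event": e, "x": x}), covariates=["x"])
        assert (not res.converged) or res.table.loc["x", "ci_high"] > 1e3

    def test_requires_events(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(df, covariates=["x"])


class TestAdministrativeCensoring:
    def test_follow_up_truncated_at_120_months(self):
        df = pd.DataFrame({"time": [50.0, 130.0, 200.0], "event": [1, 1, 0]})
        out = apply_administrative_censoring(df)
        np.testing.assert_allclose(out["time"], [50.0, 120.0, 120.0])
        np.testing.assert_array_equal(out["event"], [1, 0, 0])
        assert (out["time"] <= 120).all()


def _synthetic_clinical(rng, n, beta, cutoff=0.5, scale=150):
    scores = rng.uniform(0, 1, n)
    high = scores > cutoff
    t, e = draw_survival(rng, beta * high, SurvivalConfig(scale=scale))
    clin = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "time": t,
            "event": e,
            "grade": rng.choice([1, 2, 3], n),
            "node": rng.choice(["neg", "pos"], n),
            "size_cat": rng.choice(["<2cm", "2-5cm", ">5cm"], n),
            "pam50": rng.choice(["LumA", "Basal"], n),
            "cohort": np.where(np.arange(n) < n // 2, "discovery", "validation"),
        }
    )
    return scores, clin


class TestStratifiedAnalysis:
    def test_validation_cutoff_never_reoptimized(self):
        rng = np.random.default_rng(2)
        scores, clin = _synthetic_clinical(rng, 300, np.log(0.25))
        res = subtype_stratified_analysis(scores, clin, "pam50", "LumA")
        assert not res.get("skipped")
        assert res["discovery"]["cutoff"] == res["validation"]["cutoff"]
        assert res["discovery"]["cutoff"] == res["cutoff_result"].chosen_cutoff

    def test_sparse_subset_is_skipped(self):
        rng = np.random.default_rng(2)
        scores, clin = _synthetic_clinical(rng, 60, 0.0)
        clin.loc[clin["pam50"] == "Basal", "event"] = 0
        res = subtype_stratified_analysis(scores, clin, "pam50", "Basal", min_events=3)
        assert res.get("skipped")


class TestBootstrap:
    def test_full_fraction_reproduces_whole_cohort(self):
        rng = np.random.default_rng(31)
        scores, clin = _synthetic_clinical(rng, 120, np.log(0.3))
        cutoff = float(np.median(scores))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p_full = logrank_by_group(
                clin["time"].to_numpy(), clin["event"].to_numpy(), dichotomize(scores, cutoff)
            )
        res = bootstrap_significance(scores, clin, cutoff, fraction=1.0, n_reps=5, seed=0)
        assert res["univariate_significant_fraction"] == float(p_full < 0.05)

    def test_strong_effect_is_robustly_significant(self):
        rng = np.random.default_rng(32)
        scores, clin = _synthetic_clinical(rng, 300, np.log(0.2), scale=150)
        res = bootstrap_significance(
            scores, clin, float(np.median(scores)), fraction=0.75, n_reps=100, seed=1
        )
        assert res["univariate_significant_fraction"] > 0.95

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_significance(np.array([1.0]), pd.DataFrame(), 0.5, fraction=0.0)


class TestTissueSubsampling:
    def _counts(self, rng, n=64):
        x = rng.poisson(30, n)
        y = rng.poisson(20, n)
        cent = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        return QuadratCounts.from_arrays(x=x, y=y, centroids=cent, polygon_ids=np.arange(n))

    def test_full_fraction_recovers_slide_value(self):
        from ecoloc.indices import morisita_horn

        counts = self._counts(np.random.default_rng(3))
        res = tissue_subsampling_robustness(counts, fractions=(1.0,))
        assert res["fractions"][1.0]["values"][0] == pytest.approx(morisita_horn(counts))

    def test_homogeneous_pattern_stable_at_half_tissue(self):
        counts = self._counts(np.random.default_rng(4))
        res = tissue_subsampling_robustness(counts, fractions=(0.5,))
        assert res["fractions"][0.5]["max_abs_dev"] < 0.05

    def test_tiny_fraction_reported_missing(self):
        counts = self._counts(np.random.default_rng(5), n=4)
        res = tissue_subsampling_robustness(counts, fractions=(0.25,))
        assert np.isnan(res["fractions"][0.25]["mean"])
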