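import math

import numpy as np
import pandas as pd
import pytest

from morphomotion.stats import (
    BMI_MODELS,
    MODEL_TERMS,
    ModelFit,
    ModelSpec,
    bic,
    cohort_correlations,
    compare_models,
    fit_linear,
    model_table,
    model_table_frame,
    paired_contrast,
    partial_corr,
    pearson,
)


class TestCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 20_000))
        assert abs(pearson(x, y)) < 0.03

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))

    def test_partial_removes_common_cause(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(5000)
        x = 0.7 * z + rng.standard_normal(5000)
        y = 0.7 * z + rng.standard_normal(5000)
        assert pearson(x, y) > 0.2          # confounded
        assert abs(partial_corr(x, y, z)) < 0.05

    def test_statsmodels_cross_check(self):
        # independent route: correlation from an OLS standardized slope
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        y = 0.4 * x + rng.standard_normal(500)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        r_from_ols = res.params[1] * x.std(ddof=1) / y.std(ddof=1)
        assert pearson(x, y) == pytest.approx(r_from_ols, abs=1e-10)


class TestPairedContrast:
    def test_identical_samples_have_zero_mean_diff(self):
        a = np.array([1.0, 2.0, 3.0])
        assert paired_contrast(a, a) == (0.0, 0.0, 0.0)

    def test_constant_difference_is_degenerate(self):
        a = np.arange(5.0)
        with pytest.raises(ValueError):
            paired_contrast(a + 2.0, a)

    def test_cohen_d_by_construction(self):
        rng = np.random.default_rng(3)
        diff = rng.normal(1.528, 1.55, size=640)
        t, mean_diff, d = paired_contrast(diff, np.zeros_like(diff))
        assert d == pytest.approx(1.528 / 1.55, abs=0.12)

    def test_t_matches_scipy(self):
        from scipy import stats as sp

        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 50))
        t, _, _ = paired_contrast(a, b)
        assert t == pytest.approx(sp.ttest_rel(a, b).statistic, abs=1e-10)


def make_frame(n, seed, with_missing_bmi=True):
    from morphomotion.io import cohort_to_frame
    from morphomotion.synthetic import SimulationParams, simulate_cohort

    frac = 81 / 640 if with_missing_bmi else 0.0
    return cohort_to_frame(simulate_cohort(
        SimulationParams(n_subjects=n, seed=seed, bmi_missing_frac=frac)))


class TestFitLinear:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({
            "age_years": rng.uniform(18, 88, 50),
            "motion_movie_mm_min": rng.uniform(0.5, 5, 50),
        })
        frame["thickness_mm"] = 3.0 - 0.004 * frame.age_years - 0.01 * frame.motion_movie_mm_min
        fit = fit_linear(frame, "thickness", ("age", "motion_movie"))
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["age"] == pytest.approx(-0.004)
        assert fit.coefficients["motion_movie"] == pytest.approx(-0.01)
        assert fit.p == 3

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame({"age_years": rng.uniform(18, 88, 10_000),
                              "thickness_mm": rng.standard_normal(10_000)})
        assert fit_linear(frame, "thickness", ("age",)).r2 < 0.002

    def test_rank_deficiency_names_columns(self):
        frame = pd.DataFrame({"age_years": [1.0, 2, 3, 4, 5, 6],
                              "bmi_kg_m2": [2.0, 4, 6, 8, 10, 12],
                              "thickness_mm": [1.0, 0, 1, 0, 1, 0]})
        with pytest.raises(ValueError, match="bmi"):
            fit_linear(frame, "thickness", ("age", "bmi"))

    def test_slope_recovery_on_simulated_cohorts(self):
        from morphomotion.synthetic import SimulationParams

        p = SimulationParams()
        ages, motions = [], []
        for seed in range(100):
            fit = fit_linear(make_frame(640, seed), "thickness",
                             ("age", "motion_movie"))
            ages.append(fit.coefficients["age"])
            motions.append(fit.coefficients["motion_movie"])
        assert np.mean(ages) == pytest.approx(p.slope_thickness_per_year, rel=0.10)
        assert np.mean(motions) == pytest.approx(p.motion_effect_thickness, rel=0.10)


class TestBicMachinery:
    @staticmethod
    def fake_fit(rss, n, p, model_id=0):
        f = ModelFit(model_id=model_id, outcome="thickness", terms=("age",),
                     coefficients={}, r2=0.5, rss=rss, n=n, p=p, bic=math.nan)
        f.bic = bic(f)
        return f

    def test_extra_parameter_at_equal_rss_costs_ln_n(self):
        simple = self.fake_fit(10.0, 100, 2, model_id=1)
        complex_ = self.fake_fit(10.0, 100, 3, model_id=2)
        assert complex_.bic - simple.bic == pytest.approx(math.log(100), abs=1e-12)
        ranked = compare_models([simple, complex_])
        assert ranked[0].delta_bic == 0.0
        assert ranked[1].delta_bic == pytest.approx(math.log(100))

    def test_delta_bic_nonnegative_with_unique_zero(self):
        fits = [self.fake_fit(rss, 200, p, model_id=i)
                for i, (rss, p) in enumerate([(5.0, 2), (4.8, 3), (4.8, 4)])]
        ranked = compare_models(fits)
        deltas = [f.delta_bic for f in ranked]
        assert min(deltas) == 0.0
        assert sum(d == 0.0 for d in deltas) == 1
        assert all(d >= 0 for d in deltas)

    def test_mixed_n_comparison_rejected_by_default(self):
        with pytest.raises(ValueError, match="row counts"):
            compare_models([self.fake_fit(5.0, 100, 2), self.fake_fit(5.0, 90, 2)])

    def test_statsmodels_bic_differs_only_by_shared_constant(self):
        # ΔBIC must agree with the likelihood-based convention
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 300)
        z = rng.uniform(0, 1, 300)
        y = x + rng.standard_normal(300)
        X1 = sm.add_constant(np.column_stack([x]))
        X2 = sm.add_constant(np.column_stack([x, z]))
        r1, r2_ = sm.OLS(y, X1).fit(), sm.OLS(y, X2).fit()
        ours = (self.fake_fit(r2_.ssr, 300, 3).bic
                - self.fake_fit(r1.ssr, 300, 2).bic)
        theirs = r2_.bic - r1.bic
        assert ours == pytest.approx(theirs, abs=1e-8)


class TestModelTable:
    def test_eight_models_with_subset_n_for_bmi(self):
        frame = make_frame(640, seed=8)
        fits = model_table(frame, "thickness")
        assert [f.model_id for f in fits] == list(range(1, 9))
        for f in fits:
            expected_n = 559 if f.model_id in BMI_MODELS else 640
            assert f.n == expected_n
        # one delta-BIC zero per comparison set
        full = [f for f in fits if f.model_id not in BMI_MODELS]
        subset = [f for f in fits if f.model_id in BMI_MODELS]
        assert sum(f.delta_bic == 0.0 for f in full) == 1
        assert sum(f.delta_bic == 0.0 for f in subset) == 1

    def test_complete_bmi_gives_single_comparison_set(self):
        frame = make_frame(300, seed=9, with_missing_bmi=False)
        fits = model_table(frame, "thickness")
        assert len({f.n for f in fits}) == 1
        assert sum(f.delta_bic == 0.0 for f in fits) == 1

    def test_paper_compat_ranks_all_eight_with_warning(self):
        frame = make_frame(640, seed=10)
        with pytest.warns(UserWarning, match="not strictly comparable"):
            fits = model_table(frame, "thickness", paper_compat=True)
        assert sum(f.delta_bic == 0.0 for f in fits) == 1

    def test_r2_non_decreasing_along_nested_chains(self, cohort_frame):
        for outcome in ("thickness", "fd", "gyrification"):
            fits = {f.model_id: f for f in model_table(cohort_frame, outcome)}
            for simpler, richer in [(1, 4), (1, 5), (5, 6), (7, 8)]:
                assert fits[richer].r2 >= fits[simpler].r2 - 1e-12

    def test_generating_model_has_best_r2_among_first_five(self):
        frame = make_frame(640, seed=12)
        fits = {f.model_id: f for f in model_table(frame, "thickness")}
        full_r2 = {m: fits[m].r2 for m in (1, 4, 5)}
        assert max(full_r2, key=full_r2.get) == 5

    def test_too_few_bmi_rows_rejected(self):
        frame = make_frame(200, seed=13)
        frame["bmi_kg_m2"] = np.nan
        with pytest.raises(ValueError, match="BMI"):
            model_table(frame, "thickness")

    def test_model_spec_enforces_table_rows(self):
        with pytest.raises(ValueError):
            ModelSpec(model_id=5, outcome="thickness", terms=("age",))
        spec = ModelSpec(model_id=5, outcome="thickness",
                         terms=MODEL_TERMS[5])
        assert spec.terms == ("age", "motion_movie")

    def test_table_frame_layout(self, cohort_frame):
        table = model_table_frame(model_table(cohort_frame, "fd"))
        assert list(table.columns[:6]) == ["model_id", "terms", "n", "r2", "bic",
                                           "delta_bic"]
        assert len(table) == 8


class TestCohortCorrelations:
    def test_block_covers_headline_pairs(self, cohort_frame):
        table = cohort_correlations(cohort_frame)
        pairs = set(table["pair"])
        assert {"age~motion_rest", "motion_rest~motion_movie",
                "bmi~motion_rest|age"} <= pairs
        bmi_rows = table[table.pair.str.startswith("bmi")]
        assert (bmi_rows.n < len(cohort_frame)).all()  # missing BMI excluded
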