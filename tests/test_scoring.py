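"""Centile scores, out-of-sample offsets, trajectory and velocity curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normcharts import (
    GeneralizedGammaChart,
    StudyOffsetEstimator,
    centile_score,
    fit_new_study_offsets,
    simulate,
    trajectory,
    variability_trajectory,
    velocity,
)
from normcharts.design import DAYS_PER_YEAR
from normcharts.ggamma import gg_sample, GGParams
from normcharts.scoring import StudyOffset


class TestPredictMoments:
    def test_offset_ln2_doubles_mu(self, fitted_chart, reference_cohort):
        rows = reference_cohort.head(20)
        pop = fitted_chart.predict_moments(rows, mode="population")
        off = fitted_chart.predict_moments(rows, mode={"d_mu": np.log(2)})
        np.testing.assert_allclose(off["mu"], 2 * pop["mu"], rtol=1e-12)
        np.testing.assert_allclose(off["sigma"], pop["sigma"], rtol=1e-12)

    def test_study_mode_differs_by_exp_gamma(self, fitted_chart,
                                             reference_cohort):
        rows = reference_cohort[reference_cohort["study"] == "S003"].head(10)
        pop = fitted_chart.predict_moments(rows, mode="population")
        stu = fitted_chart.predict_moments(rows, mode="study")
        g = fitted_chart.gamma_mu_["S003"]
        np.testing.assert_allclose(stu["mu"], pop["mu"] * np.exp(g),
                                   rtol=1e-12)

    def test_manual_dot_product_oracle(self, gmv_truth):
        # hand-computed linear predictor for one toy row
        chart = simulate.chart_from_truth(gmv_truth)
        x = 1.0
        row = pd.DataFrame({
            "participant_id": ["t"], "study": ["S000"],
            "age_days": [x * DAYS_PER_YEAR], "sex": ["F"], "version": ["v1"],
        })
        got = chart.predict_moments(row, mode="population")
        b = gmv_truth.beta_mu
        # at x=1: log x = 0, so both FP columns vanish; sex F contributes 0
        assert got["mu"].iloc[0] == pytest.approx(np.exp(b[0]), rel=1e-12)
        assert got["sigma"].iloc[0] == pytest.approx(
            np.exp(gmv_truth.beta_sigma[0]), rel=1e-12)

    def test_unknown_study_suggests_offset_mode(self, fitted_chart,
                                                reference_cohort):
        rows = reference_cohort.head(3).assign(study="UNSEEN")
        with pytest.raises(ValueError, match="offset mode"):
            fitted_chart.predict_moments(rows, mode="study")


class TestCentileScore:
    def test_median_maps_to_half(self, fitted_chart, reference_cohort):
        rows = reference_cohort.head(50).copy()
        pred = fitted_chart.predict_moments(rows, mode="population")
        from normcharts.ggamma import quantile_arrays
        rows["GMV"] = quantile_arrays(0.5, pred["mu"].to_numpy(),
                                      pred["sigma"].to_numpy(),
                                      pred["nu"].to_numpy())
        cent = centile_score(fitted_chart, rows, mode="population")
        np.testing.assert_allclose(cent["centile"], 0.5, atol=1e-10)

    def test_extreme_value_monotonicity(self, fitted_chart, reference_cohort):
        rows = reference_cohort.head(20).copy()
        pred = fitted_chart.predict_moments(rows, mode="population")
        from normcharts.ggamma import quantile_arrays
        q975 = quantile_arrays(0.975, pred["mu"].to_numpy(),
                               pred["sigma"].to_numpy(),
                               pred["nu"].to_numpy())
        rows["GMV"] = 10.0 * q975
        cent = centile_score(fitted_chart, rows, mode="population")
        assert np.all(cent["centile"] >= 0.975)

    def test_in_model_centiles_uniform(self, fitted_chart, reference_cohort):
        cent = centile_score(fitted_chart, reference_cohort.head(2000),
                             mode="study")
        assert stats.kstest(cent["centile"], "uniform").pvalue > 0.01

    def test_clamping_and_row_count(self, fitted_chart, reference_cohort):
        rows = reference_cohort.head(5).assign(GMV=1e-3)  # absurdly small
        cent = centile_score(fitted_chart, rows, mode="population")
        assert len(cent) == 5
        assert np.all(cent["centile"] >= 1e-6)

    def test_unit_invariance_after_refit(self, gmv_truth, small_cohort):
        opts = dict(tol=1e-10, inner_gtol=1e-11)
        a = GeneralizedGammaChart(spec=gmv_truth.spec, **opts).fit(
            small_cohort)
        ml = small_cohort.assign(GMV=small_cohort["GMV"] / 1000.0)  # mm3->ml
        b = GeneralizedGammaChart(spec=gmv_truth.spec, **opts).fit(ml)
        ca = centile_score(a, small_cohort, mode="study")["centile"]
        cb = centile_score(b, ml, mode="study")["centile"]
        np.testing.assert_allclose(ca, cb, atol=1e-6)


class TestOffsets:
    def test_zero_offset_null_case(self, gmv_truth, fitted_chart):
        # median estimate across replicate studies (SE of a single-study
        # d_sigma is ~1/sqrt(2n), comparable to the tolerance)
        d_mus, d_sis = [], []
        for r in range(9):
            new = simulate.make_new_study(
                gmv_truth, {"d_mu": 0.0, "d_sigma": 0.0}, 500,
                seed=300 + r, study="NEW")
            off = fit_new_study_offsets(fitted_chart, new, estimate_nu=False)
            d_mus.append(off.d_mu)
            d_sis.append(off.d_sigma)
        assert abs(np.median(d_mus)) < 0.02
        assert abs(np.median(d_sis)) < 0.02

    def test_small_sample_warning_threshold(self, gmv_truth, fitted_chart):
        new = simulate.make_new_study(gmv_truth, {"d_mu": 0.0}, 80, seed=1)
        off = fit_new_study_offsets(fitted_chart, new)
        assert off.small_sample_warning is True
        assert off.n_scans == 80
        new2 = simulate.make_new_study(gmv_truth, {"d_mu": 0.0}, 120, seed=1)
        assert fit_new_study_offsets(
            fitted_chart, new2).small_sample_warning is False

    def test_overlapping_study_rejected(self, fitted_chart, reference_cohort):
        with pytest.raises(ValueError, match="already in the model"):
            StudyOffsetEstimator(fitted_chart).fit(reference_cohort.head(50))

    def test_multiple_new_studies(self, gmv_truth, fitted_chart):
        a = simulate.make_new_study(gmv_truth, {"d_mu": 0.1}, 150, seed=2,
                                    study="NEW_A")
        b = simulate.make_new_study(gmv_truth, {"d_mu": -0.1}, 150, seed=3,
                                    study="NEW_B")
        offs = fit_new_study_offsets(fitted_chart,
                                     pd.concat([a, b], ignore_index=True),
                                     estimate_nu=False)
        assert set(offs) == {"NEW_A", "NEW_B"}
        assert offs["NEW_A"].d_mu > offs["NEW_B"].d_mu


class TestTrajectory:
    def test_median_is_level_half(self, fitted_chart):
        grid = np.linspace(1.0, 80.0, 50)
        tr = trajectory(fitted_chart, "F", grid, levels=(0.5,))
        params = fitted_chart.predict_moments(
            pd.DataFrame({"participant_id": "g", "study": "S000",
                          "age_days": grid * DAYS_PER_YEAR,
                          "sex": "F",
                          "version": fitted_chart.registry_.version_levels[0]}),
            mode="population")
        from normcharts.ggamma import quantile_arrays
        np.testing.assert_allclose(
            tr["c0.5"],
            quantile_arrays(0.5, params["mu"].to_numpy(),
                            params["sigma"].to_numpy(),
                            params["nu"].to_numpy()), rtol=1e-12)

    def test_levels_do_not_cross(self, fitted_chart):
        grid = np.linspace(0.4, 95.0, 200)
        tr = trajectory(fitted_chart, "M", grid,
                        levels=(0.025, 0.5, 0.975))
        assert np.all(tr["c0.975"] >= tr["c0.5"])
        assert np.all(tr["c0.5"] >= tr["c0.025"])

    def test_offset_doubles_curves(self, fitted_chart):
        grid = np.linspace(1.0, 50.0, 30)
        base = trajectory(fitted_chart, "F", grid, levels=(0.5,))
        off = trajectory(fitted_chart, "F", grid, levels=(0.5,),
                         mode={"d_mu": np.log(2.0)})
        np.testing.assert_allclose(off["c0.5"], 2 * base["c0.5"], rtol=1e-12)

    def test_empty_grid_rejected(self, fitted_chart):
        with pytest.raises(ValueError, match="non-empty"):
            trajectory(fitted_chart, "F", [])

    def test_extrapolation_flag(self, fitted_chart):
        lo, hi = fitted_chart.age_support_
        tr = trajectory(fitted_chart, "F", [lo + 1.0, hi + 5.0])
        assert list(tr["extrapolated"]) == [False, True]


class TestVariability:
    def test_exponential_sd_equals_mu(self):
        truth = simulate.preset("gmv_like", sigma0=1.0, nu=1.0)
        chart = simulate.chart_from_truth(truth)
        grid = np.array([1.0, 6.67, 30.0])
        sd = variability_trajectory(chart, "F", grid)["sd"].to_numpy()
        mu = chart.predict_moments(
            pd.DataFrame({"participant_id": "g", "study": "S000",
                          "age_days": grid * DAYS_PER_YEAR, "sex": "F",
                          "version": "v1"}), mode="population")["mu"]
        np.testing.assert_allclose(sd, mu, rtol=1e-9)

    def test_sd_matches_sampling_oracle(self, gmv_truth):
        chart = simulate.chart_from_truth(gmv_truth)
        grid = np.array([2.0, 6.67, 60.0])
        sd = variability_trajectory(chart, "M", grid)["sd"].to_numpy()
        params = chart.predict_moments(
            pd.DataFrame({"participant_id": "g", "study": "S000",
                          "age_days": grid * DAYS_PER_YEAR, "sex": "M",
                          "version": "v1"}), mode="population")
        for k in range(3):
            s = gg_sample(100_000, GGParams(params["mu"].iloc[k],
                                            params["sigma"].iloc[k],
                                            params["nu"].iloc[k]), 50 + k)
            assert sd[k] == pytest.approx(s.std(), rel=0.01)

    def test_offset_scales_sd(self, gmv_truth):
        chart = simulate.chart_from_truth(gmv_truth)
        grid = np.array([5.0, 20.0])
        base = variability_trajectory(chart, "F", grid)["sd"]
        off = variability_trajectory(chart, "F", grid,
                                     mode={"d_mu": 0.4})["sd"]
        np.testing.assert_allclose(off, np.exp(0.4) * base, rtol=1e-9)


class TestVelocity:
    def test_constant_curve_zero(self):
        g = np.linspace(0, 10, 11)
        np.testing.assert_array_equal(velocity(g, np.full(11, 3.0)), 0.0)

    def test_quadratic_exact_interior(self):
        g = np.linspace(0, 10, 21)
        v = velocity(g, g ** 2)
        np.testing.assert_allclose(v[1:-1], 2 * g[1:-1], rtol=1e-12)

    def test_duplicate_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            velocity(np.array([1.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))

    def test_matches_analytic_fp_derivative(self, gmv_truth):
        # d/dx exp(a + b1 ln x + b2 ln^2 x) has a closed form; a daily grid
        # central difference must agree to O(h^2)
        chart = simulate.chart_from_truth(gmv_truth)
        grid = np.arange(2.0, 10.0, 1.0 / DAYS_PER_YEAR)
        tr = trajectory(chart, "F", grid, levels=(0.5,))
        v = velocity(grid, tr["c0.5"].to_numpy())
        a, _, b1, b2 = gmv_truth.beta_mu
        m = np.exp(a + b1 * np.log(grid) + b2 * np.log(grid) ** 2)
        # the median is mu times a constant quantile factor q(sigma, nu)
        from normcharts.ggamma import quantile_arrays
        q = quantile_arrays(0.5, 1.0, np.exp(gmv_truth.beta_sigma[0]),
                            gmv_truth.alpha_nu)
        analytic = q * m * (b1 + 2 * b2 * np.log(grid)) / grid
        np.testing.assert_allclose(
            v[1:-1], analytic[1:-1], rtol=1e-4,
            atol=1e-6 * np.max(np.abs(analytic)))
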