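"""Cubic time-course regression, DDP calling, bootstrap bands."""

import numpy as np
import pandas as pd
import pytest

from promdyn import (
    DynamicPromoterDetector,
    bootstrap_trajectory,
    call_ddps,
    compare_ddp_vs_flat,
    fit_timecourse,
    stage_mean_profiles,
)


def times_16x2():
    return np.repeat(np.arange(16, dtype=float), 2)


class TestFitTimecourse:
    def test_constant_activity(self):
        fit = fit_timecourse(times_16x2(), np.full(32, 2.5))
        assert fit["r_squared"] == 0.0
        assert fit["beta1"] == fit["beta2"] == fit["beta3"] == 0.0
        assert fit["p_value"] == 1.0
        assert fit["delta_fit"] == 0.0

    def test_noiseless_cubic_r2_is_one(self):
        t = times_16x2()
        z = (t - t.mean()) / t.std()
        y = 1.0 + 0.5 * z - 0.2 * z**2 + 0.1 * z**3
        fit = fit_timecourse(t, y)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert fit["p_value"] == 0.0
        assert fit["beta3"] == pytest.approx(0.1, abs=1e-9)

    def test_too_few_distinct_times_raises(self):
        with pytest.raises(ValueError, match="distinct time points"):
            fit_timecourse(np.array([0.0, 0, 1, 1, 2, 2]), np.arange(6.0))

    def test_missing_values_dropped_pairwise(self):
        t = times_16x2()
        y = 0.3 * t
        y_na = y.copy()
        y_na[5] = np.nan
        fit = fit_timecourse(t, y_na)
        assert fit["n_obs"] == 31
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_statsmodels_ols(self):
        """Independent oracle: statsmodels OLS on the same design."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        t = times_16x2()
        z = (t - t.mean()) / t.std()
        X = sm.add_constant(np.column_stack([z, z**2, z**3]))
        for _ in range(20):
            y = rng.normal(size=len(t)) + rng.normal() * z
            fit = fit_timecourse(t, y)
            res = sm.OLS(y, X).fit()
            np.testing.assert_allclose(
                [fit[f"beta{i}"] for i in range(4)], res.params, atol=1e-8
            )
            assert fit["r_squared"] == pytest.approx(res.rsquared, abs=1e-8)
            assert fit["p_value"] == pytest.approx(res.f_pvalue, abs=1e-8)

    def test_r2_invariant_to_affine_time_rescale(self):
        rng = np.random.default_rng(1)
        t = times_16x2()
        y = rng.normal(size=len(t)) + 0.1 * t
        f1 = fit_timecourse(t, y)
        f2 = fit_timecourse(7.0 * t + 3.0, y)
        assert f1["r_squared"] == pytest.approx(f2["r_squared"], abs=1e-10)
        assert f1["p_value"] == pytest.approx(f2["p_value"], abs=1e-10)
        assert f1["delta_fit"] == pytest.approx(f2["delta_fit"], abs=1e-10)


class TestCallDdps:
    def fits_df(self, rows):
        return pd.DataFrame(rows).set_index("promoter_id")

    def test_r2_boundary(self):
        fits = self.fits_df(
            [
                dict(promoter_id="at", p_value=1e-6, r_squared=0.30, delta_fit=1.0),
                dict(promoter_id="below", p_value=1e-6, r_squared=0.29, delta_fit=1.0),
            ]
        )
        out = call_ddps(fits, alpha=0.05)
        assert bool(out.loc["at", "is_ddp"]) is True
        assert bool(out.loc["below", "is_ddp"]) is False
        assert out.loc["below", "direction"] == "Flat"

    def test_direction_from_fitted_endpoints(self):
        fits = self.fits_df(
            [
                dict(promoter_id="up", p_value=1e-9, r_squared=0.9, delta_fit=1.7),
                dict(promoter_id="down", p_value=1e-9, r_squared=0.9, delta_fit=-0.4),
                dict(promoter_id="hump", p_value=1e-9, r_squared=0.9, delta_fit=0.0),
            ]
        )
        out = call_ddps(fits)
        assert list(out["direction"]) == ["Up", "Down", "Flat"]

    def test_skipped_promoters_stay_flat_and_untested(self):
        fits = self.fits_df(
            [
                dict(promoter_id="ok", p_value=1e-9, r_squared=0.9, delta_fit=1.0),
                dict(promoter_id="skip", p_value=np.nan, r_squared=np.nan,
                     delta_fit=np.nan),
            ]
        )
        out = call_ddps(fits)
        assert bool(out.loc["skip", "is_ddp"]) is False
        assert np.isnan(out.loc["skip", "q_value"])


class TestDetector:
    def test_planted_trend_called_noise_not(self):
        rng = np.random.default_rng(0)
        t = times_16x2()
        z = (t - t.mean()) / t.std()
        X = pd.DataFrame(
            {
                "trend": 5 + 2.0 * z + rng.normal(0, 0.3, len(t)),
                "noise": 5 + rng.normal(0, 0.3, len(t)),
            }
        ).T
        X.columns = [f"s{i}" for i in range(len(t))]
        det = DynamicPromoterDetector().fit(X, t)
        assert det.results_.loc["trend", "is_ddp"]
        assert det.results_.loc["trend", "direction"] == "Up"
        assert not det.results_.loc["noise", "is_ddp"]
        assert det.predict(["noise"]).iloc[0] == "Flat"

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(2)
        t = times_16x2()
        z = (t - t.mean()) / t.std()
        rates = []
        for effect in (0.2, 0.6, 1.8):
            X = pd.DataFrame(
                effect * z + rng.normal(0, 1.0, size=(150, len(t))),
                columns=[f"s{i}" for i in range(len(t))],
            )
            det = DynamicPromoterDetector().fit(X, t)
            rates.append(det.results_["is_ddp"].mean())
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9

    def test_sparse_promoters_skipped_with_reason(self):
        t = times_16x2()
        row = np.full(len(t), np.nan)
        row[:4] = [1, 2, 3, 4]
        X = pd.DataFrame([row], index=["sparse"],
                         columns=[f"s{i}" for i in range(len(t))])
        det = DynamicPromoterDetector().fit(X, t)
        assert "present" in det.results_.loc["sparse", "skip_reason"]
        assert not det.results_.loc["sparse", "is_ddp"]


def test_detector_supports_sklearn_param_api():
    from sklearn.base import clone

    det = DynamicPromoterDetector(alpha=0.1, r2_min=0.4)
    cloned = clone(det)
    assert cloned.get_params()["alpha"] == 0.1
    cloned.set_params(r2_min=0.2)
    assert cloned.r2_min == 0.2


class TestBootstrap:
    def test_single_constant_promoter_zero_width(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=[0, 1, 2])
        band = bootstrap_trajectory(prof, n_boot=100, seed=0)
        np.testing.assert_allclose(band["lower"], band["upper"])
        np.testing.assert_allclose(band["mean"], [1, 2, 3])

    def test_band_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.normal(size=(30, 5)))
        band = bootstrap_trajectory(prof, n_boot=500, seed=1)
        assert (band["lower"] <= band["mean"] + 1e-12).all()
        assert (band["upper"] >= band["mean"] - 1e-12).all()

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.normal(size=(20, 4)))
        b1 = bootstrap_trajectory(prof, n_boot=200, seed=9)
        b2 = bootstrap_trajectory(prof, n_boot=200, seed=9)
        pd.testing.assert_frame_equal(b1, b2)

    def test_coverage_close_to_nominal(self):
        """~95% of bootstrap bands should contain the true ensemble mean."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 150
        for _ in range(reps):
            prof = pd.DataFrame(rng.normal(0.0, 1.0, size=(40, 1)))
            band = bootstrap_trajectory(prof, n_boot=300, seed=int(rng.integers(2**31)))
            hits += band["lower"].iloc[0] <= 0.0 <= band["upper"].iloc[0]
        assert 0.85 <= hits / reps <= 0.99


class TestDdpVsFlat:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(8)
        prof = pd.DataFrame(rng.normal(size=(200, 6)))
        prof.iloc[:100] += 2.0
        is_ddp = pd.Series([True] * 100 + [False] * 100, index=prof.index)
        res = compare_ddp_vs_flat(prof, is_ddp)
        assert (res["p_value"] < 0.05).all()
        assert (res["median_ddp"] > res["median_flat"]).all()

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(100):
            prof = pd.DataFrame(rng.normal(size=(40, 4)))
            is_ddp = pd.Series([True] * 20 + [False] * 20, index=prof.index)
            pvals.append(compare_ddp_vs_flat(prof, is_ddp).loc["mean", "p_value"])
        assert 0.2 <= np.mean(np.array(pvals) < 0.5) <= 0.8
        assert np.mean(np.array(pvals) < 0.05) <= 0.15

    def test_one_vs_one_degenerate(self):
        prof = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"])
        res = compare_ddp_vs_flat(prof, pd.Series({"a": True, "b": False}))
        assert res["p_value"].notna().all()

    def test_empty_group_warns(self):
        prof = pd.DataFrame([[1.0, 2.0]], index=["a"])
        with pytest.warns(UserWarning, match="empty"):
            res = compare_ddp_vs_flat(prof, pd.Series({"a": True}))
        assert res["p_value"].isna().all()


def test_stage_mean_profiles_averages_replicates():
    act = pd.DataFrame(
        [[1.0, 3.0, 10.0, 20.0]], index=["p"], columns=["a1", "a2", "b1", "b2"]
    )
    stages = pd.Series({"a1": 0, "a2": 0, "b1": 1, "b2": 1})
    prof = stage_mean_profiles(act, stages)
    np.testing.assert_allclose(prof.loc["p"], [2.0, 15.0])
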