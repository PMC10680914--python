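"""Per-disease polynomial trajectory fits, CIs, and degree diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cbvolz import compare_degrees, confidence_band, fit_trajectory, fits_to_frame
from cbvolz.exceptions import FitError, InsufficientDataError
from cbvolz.normative import ZScoreTable

from helpers import ols_normal_equations


def z_table(groups, durations, zs, region="cwm", sara=None):
    n = len(zs)
    df = pd.DataFrame(
        {
            "subject_id": [f"p{i}" for i in range(n)],
            "group": groups if isinstance(groups, list) else [groups] * n,
            "age": 55.0,
            "sex": "F",
            "duration": durations,
            "sara": sara if sara is not None else [10.0] * n,
            "etiv": 1.5e6,
            region: zs,
        }
    )
    return ZScoreTable(
        data=df,
        extrapolated=pd.DataFrame({region: [False] * n}),
        region_schema=[region],
        reference_group="HC",
    )


class TestFitTrajectory:
    def test_two_points_interpolated_exactly(self):
        z = z_table("SCA3", [0.0, 10.0], [-1.0, -3.0])
        fit = fit_trajectory(z, "SCA3", "cwm", "duration", degree=1)
        assert fit.coefficients[0] == pytest.approx(-1.0, abs=1e-12)
        assert fit.coefficients[1] == pytest.approx(-0.2, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_gives_zero_slope_and_r2(self):
        z = z_table("SCA3", [1.0, 4.0, 7.0, 9.0], [-2.0] * 4)
        fit = fit_trajectory(z, "SCA3", "cwm", "duration", degree=1)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0
        assert fit.slope_p == 1.0

    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_matches_normal_equations_oracle(self, rng, degree):
        for _ in range(25):
            n = int(rng.integers(degree + 3, 40))
            x = rng.uniform(0, 15, n)
            y = -1 + -0.2 * x + rng.normal(0, 0.5, n)
            z = z_table("SCA3", x, y)
            fit = fit_trajectory(z, "SCA3", "cwm", "duration", degree=degree)
            beta, r2, p, cov = ols_normal_equations(x, y, degree)
            np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-10)
            assert fit.r_squared == pytest.approx(r2, rel=1e-10)
            if degree == 1:
                assert fit.slope_p == pytest.approx(p, rel=1e-10)
            np.testing.assert_allclose(fit.cov_params, cov, rtol=1e-8)

    def test_fitted_plus_residuals_reconstruct_observations(self, rng):
        x = rng.uniform(0, 20, 30)
        y = rng.normal(-2, 1, 30)
        fit = fit_trajectory(z_table("SCA3", x, y), "SCA3", "cwm", "duration")
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-12)

    def test_r_squared_non_decreasing_in_degree(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 15, 20)
            y = rng.normal(0, 1, 20)
            z = z_table("SCA3", x, y)
            r2 = [
                fit_trajectory(z, "SCA3", "cwm", "duration", degree=d).r_squared
                for d in (1, 2, 3)
            ]
            assert r2[0] <= r2[1] + 1e-12 and r2[1] <= r2[2] + 1e-12

    def test_covariate_shift_changes_only_intercept(self, rng):
        x = rng.uniform(0, 15, 25)
        y = -1 - 0.2 * x + rng.normal(0, 0.4, 25)
        f0 = fit_trajectory(z_table("SCA3", x, y), "SCA3", "cwm", "duration")
        f1 = fit_trajectory(z_table("SCA3", x + 5.0, y), "SCA3", "cwm", "duration")
        assert f1.coefficients[1] == pytest.approx(f0.coefficients[1], rel=1e-9)
        assert f1.r_squared == pytest.approx(f0.r_squared, rel=1e-9)
        assert f1.slope_p == pytest.approx(f0.slope_p, rel=1e-9)
        assert f1.coefficients[0] != pytest.approx(f0.coefficients[0], rel=1e-3)

    def test_insufficient_records_raise_naming_context(self):
        z = z_table("SCA1", [3.0], [-1.0])
        with pytest.raises(InsufficientDataError, match="SCA1/cwm"):
            fit_trajectory(z, "SCA1", "cwm", "duration")

    def test_zero_covariate_variance_raises(self):
        z = z_table("SCA3", [5.0] * 6, [-1, -2, -1.5, -2.5, -1, -2])
        with pytest.raises(FitError, match="variance"):
            fit_trajectory(z, "SCA3", "cwm", "duration")

    def test_reference_group_is_not_fittable(self, ztable):
        with pytest.raises(FitError):
            fit_trajectory(ztable, "HC", "cwm", "duration")

    def test_missing_covariate_dropped_complete_case(self):
        z = z_table("SCA3", [1, 2, np.nan, 4, 5, 6], [-1, -1.2, -1.4, -1.6, -1.8, -2])
        fit = fit_trajectory(z, "SCA3", "cwm", "duration")
        assert fit.n == 5


class TestConfidenceBand:
    def _fit(self, rng, n=30):
        x = rng.uniform(0, 15, n)
        y = -1 - 0.2 * x + rng.normal(0, 0.5, n)
        return fit_trajectory(z_table("SCA3", x, y), "SCA3", "cwm", "duration")

    def test_band_narrowest_at_covariate_mean(self, rng):
        fit = self._fit(rng)
        grid = np.linspace(fit.x_range[0], fit.x_range[1], 101)
        lo, hi = confidence_band(fit, grid)
        width = hi - lo
        xbar = fit.x.mean()
        assert abs(grid[np.argmin(width)] - xbar) <= (grid[1] - grid[0]) * 2

    def test_higher_level_gives_wider_band(self, rng):
        fit = self._fit(rng)
        grid = np.linspace(0, 15, 20)
        lo95, hi95 = confidence_band(fit, grid, 0.95)
        lo99, hi99 = confidence_band(fit, grid, 0.99)
        assert ((hi99 - lo99) > (hi95 - lo95)).all()

    def test_band_at_mean_matches_closed_form(self, rng):
        """At x̄ the mean-response CI is fitted(x̄) ± t · s / sqrt(n)."""
        fit = self._fit(rng)
        xbar = fit.x.mean()
        lo, hi = confidence_band(fit, [xbar], 0.95)
        s = np.sqrt(fit.resid_var)
        t = scipy.stats.t.ppf(0.975, fit.n - 2)
        half = t * s / np.sqrt(fit.n)
        mu = fit.predict(xbar)[0]
        assert lo[0] == pytest.approx(mu - half, rel=1e-9)
        assert hi[0] == pytest.approx(mu + half, rel=1e-9)

    def test_band_symmetric_about_fitted_line(self, rng):
        fit = self._fit(rng)
        grid = np.linspace(0, 15, 20)
        lo, hi = confidence_band(fit, grid)
        np.testing.assert_allclose((lo + hi) / 2, fit.predict(grid), atol=1e-12)

    def test_invalid_level_raises(self, rng):
        fit = self._fit(rng)
        with pytest.raises(ValueError):
            confidence_band(fit, [5.0], level=1.5)


class TestCompareDegrees:
    def test_aic_favors_line_on_linear_data(self, rng):
        wins = 0
        reps = 40
        for _ in range(reps):
            x = rng.uniform(0, 15, 30)
            y = -1 - 0.2 * x + rng.normal(0, 0.5, 30)
            bundle = compare_degrees(z_table("SCA3", x, y), "SCA3", "cwm", "duration")
            if min(bundle.aic, key=bundle.aic.get) == 1:
                wins += 1
        assert wins > reps / 2

    def test_small_n_limits_feasible_degrees(self):
        z = z_table("SCA1", [1.0, 3.0, 6.0, 9.0], [-1, -1.5, -2, -2.2])
        bundle = compare_degrees(z, "SCA1", "cwm", "duration")
        assert sorted(bundle.fits) == [1, 2]
        assert bundle.infeasible_degrees == [3]

    def test_diagnostics_bookkeeping(self, rng):
        x = rng.uniform(0, 15, 25)
        y = rng.normal(-2, 1, 25)
        bundle = compare_degrees(z_table("SCA3", x, y), "SCA3", "cwm", "duration")
        for d, rvf in bundle.residual_vs_fitted.items():
            assert len(rvf) == 25
            qq = bundle.qq[d]
            assert len(qq) == 25
            assert (np.diff(qq["theoretical"]) > 0).all()


def test_fit_table_has_bh_adjusted_extension_column(ztable):
    fits = [
        fit_trajectory(ztable, d, r, "duration")
        for d in ztable.disease_groups()
        for r in ztable.region_schema
    ]
    table = fits_to_frame(fits)
    assert "slope_p_bh" in table.columns
    valid = table.dropna(subset=["slope_p_bh"])
    assert (valid["slope_p_bh"] >= valid["slope_p"] - 1e-12).all()
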