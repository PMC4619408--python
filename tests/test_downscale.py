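"""Lapse-rate regression, elevation-adjusted interpolation, anomalies, spin-up."""

import numpy as np
import pytest

from finedgvm.downscale import (
    apply_anomalies,
    build_spinup,
    cloud_to_sunshine,
    compute_anomalies,
    fit_local_lapse_rates,
    interpolate_series,
    interpolate_with_lapse,
)
from finedgvm.fields import ClimatologyField, LapseRateField, MonthlySeries
from finedgvm.grid import ElevationField, build_grid

LAPSE = -0.0065  # degC per metre


def _terrain(grid, rng=None, relief=1500.0):
    if rng is None:
        z = np.zeros(grid.shape)
    else:
        z = relief * rng.random(grid.shape)
    return ElevationField(grid=grid, values=z)


def _linear_tclim(grid, elev, sea_level=20.0, lapse=LAPSE, noise_sd=0.0, rng=None):
    values = np.empty((12,) + grid.shape)
    for m in range(12):
        values[m] = sea_level + lapse * elev.values
        if noise_sd and rng is not None:
            values[m] += rng.normal(0.0, noise_sd, grid.shape)
    return ClimatologyField("tmean", values, grid=grid)


class TestLapseRates:
    def test_exact_linear_field_recovers_slope(self):
        grid = build_grid(40.0, 45.0, -120.0, -115.0, 0.5)
        elev = _terrain(grid, np.random.default_rng(0))
        clim = _linear_tclim(grid, elev)
        lapse = fit_local_lapse_rates(clim, elev, window_radius=2, min_points=5)
        np.testing.assert_allclose(lapse.values, LAPSE, atol=1e-12)

    def test_constant_field_gives_zero_slope(self):
        grid = build_grid(40.0, 45.0, -120.0, -115.0, 0.5)
        elev = _terrain(grid, np.random.default_rng(1))
        clim = ClimatologyField("tmean", np.full((12,) + grid.shape, 8.0), grid=grid)
        lapse = fit_local_lapse_rates(clim, elev, window_radius=2, min_points=5)
        np.testing.assert_allclose(lapse.values, 0.0, atol=1e-12)

    def test_noisy_recovery_within_five_percent(self):
        """Mean |slope error| < 5% at noise sd 0.5 degC over ~1000 cells."""
        grid = build_grid(40.0, 48.0, -124.0, -108.0, 0.5)  # 16x32 = 512 cells
        rng = np.random.default_rng(12345)
        elev = _terrain(grid, rng)
        clim = _linear_tclim(grid, elev, noise_sd=0.5, rng=rng)
        lapse = fit_local_lapse_rates(clim, elev, window_radius=4, min_points=10)
        err = np.abs(lapse.values - LAPSE) / abs(LAPSE)
        assert np.nanmean(err) < 0.05

    def test_small_window_is_masked(self):
        grid = build_grid(40.0, 41.0, -120.0, -119.0, 0.5)  # 2x2 cells
        elev = _terrain(grid, np.random.default_rng(2))
        clim = _linear_tclim(grid, elev)
        lapse = fit_local_lapse_rates(clim, elev, window_radius=1, min_points=10)
        assert lapse.mask.all()


class TestInterpolateWithLapse:
    def _setup(self, ratio=3):
        coarse = build_grid(40.0, 44.0, -120.0, -116.0, 0.5)
        fine = build_grid(40.0, 44.0, -120.0, -116.0, 0.5 / ratio)
        return coarse, fine

    def test_coincident_node_equal_elevation_exact(self):
        """Odd refinement ratios put fine centres on coarse nodes."""
        coarse, fine = self._setup(ratio=3)
        rng = np.random.default_rng(3)
        z_c = _terrain(coarse, rng)
        clim = _linear_tclim(coarse, z_c)
        lapse = LapseRateField("tmean", np.full((12,) + coarse.shape, LAPSE), grid=coarse)
        # fine elevation equal to the containing coarse cell's elevation
        z_f = ElevationField(
            grid=fine, values=np.repeat(np.repeat(z_c.values, 3, 0), 3, 1)
        )
        out = interpolate_with_lapse(clim, lapse, fine, z_f, z_c)
        # fine centre (1 + 3i, 1 + 3j) coincides with coarse node (i, j)
        sub = out.values[:, 1::3, 1::3]
        np.testing.assert_array_equal(sub, clim.values)

    def test_constant_nodes_zero_lapse_constant_everywhere(self):
        coarse, fine = self._setup()
        z_c = _terrain(coarse)
        clim = ClimatologyField("tmean", np.full((12,) + coarse.shape, 4.5), grid=coarse)
        lapse = LapseRateField("tmean", np.zeros((12,) + coarse.shape), grid=coarse)
        z_f = _terrain(fine)
        out = interpolate_with_lapse(clim, lapse, fine, z_f, z_c)
        inner = out.values[:, ~np.isnan(out.values[0])]
        np.testing.assert_allclose(inner, 4.5, atol=1e-12)

    def test_analytic_lapse_field_reconstructed(self):
        """T = C + L*z is reproduced at every unmasked fine point."""
        coarse, fine = self._setup()
        rng = np.random.default_rng(4)
        z_c = _terrain(coarse, rng)
        clim = _linear_tclim(coarse, z_c, sea_level=15.0)
        lapse = LapseRateField("tmean", np.full((12,) + coarse.shape, LAPSE), grid=coarse)
        z_f = _terrain(fine, rng)
        out = interpolate_with_lapse(clim, lapse, fine, z_f, z_c)
        expected = 15.0 + LAPSE * z_f.values
        ok = ~np.isnan(out.values[0])
        np.testing.assert_allclose(out.values[:, ok], np.broadcast_to(expected, (12,) + fine.shape)[:, ok], atol=1e-6)

    def test_outside_hull_masked(self):
        coarse, fine = self._setup()
        z_c = _terrain(coarse)
        clim = _linear_tclim(coarse, z_c)
        lapse = LapseRateField("tmean", np.zeros((12,) + coarse.shape), grid=coarse)
        z_f = _terrain(fine)
        out = interpolate_with_lapse(clim, lapse, fine, z_f, z_c)
        assert np.isnan(out.values[:, 0, 0]).all()  # outside the node hull
        assert np.isfinite(out.values[:, 10, 10]).all()


class TestAnomalies:
    def _base(self, grid, variable="tmean", value=10.0):
        return ClimatologyField(variable, np.full((12,) + grid.shape, value), grid=grid)

    def _series(self, grid, variable="tmean", value=12.0, ny=3):
        return MonthlySeries(
            variable, np.full((ny, 12) + grid.shape, value), years=(2001, 2000 + ny),
            grid=grid,
        )

    def test_difference_definitional(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        anoms = compute_anomalies(self._series(grid), self._base(grid), "difference")
        np.testing.assert_allclose(anoms.values, 2.0)
        assert anoms.mode == "anomaly-difference"

    def test_ratio_definitional(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        anoms = compute_anomalies(
            self._series(grid, "precip", 50.0), self._base(grid, "precip", 100.0),
            "ratio",
        )
        np.testing.assert_allclose(anoms.values, 0.5)

    def test_zero_base_ratio_rule(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        base = self._base(grid, "precip", 0.0)
        anoms = compute_anomalies(self._series(grid, "precip", 7.0), base, "ratio")
        np.testing.assert_allclose(anoms.values, 1.0)

    def test_mode_variable_mismatch_raises(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        with pytest.raises(ValueError, match="mode"):
            compute_anomalies(self._series(grid), self._base(grid), "ratio")

    @pytest.mark.parametrize("variable,mode", [("tmean", "difference"), ("precip", "ratio")])
    def test_round_trip_identity(self, variable, mode, rng):
        grid = build_grid(0.0, 2.0, 0.0, 2.0, 0.5)
        base_vals = rng.uniform(20.0, 80.0, (12,) + grid.shape)
        base = ClimatologyField(variable, base_vals, grid=grid)
        series_vals = rng.uniform(20.0, 80.0, (4, 12) + grid.shape)
        series = MonthlySeries(variable, series_vals, years=(1961, 1964), grid=grid)
        anoms = compute_anomalies(series, base, mode)
        back = apply_anomalies(base, anoms)
        np.testing.assert_allclose(back.values, series.values, atol=1e-9)

    def test_sunshine_clamped_at_100(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        base = self._base(grid, "sunshine", 95.0)
        anoms = MonthlySeries(
            "sunshine", np.full((1, 12) + grid.shape, 1.2), years=(2050, 2050),
            mode="anomaly-ratio", grid=grid,
        )
        out = apply_anomalies(base, anoms)
        np.testing.assert_allclose(out.values, 100.0)

    def test_precip_ratio_applied(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        base = self._base(grid, "precip", 80.0)
        anoms = MonthlySeries(
            "precip", np.full((1, 12) + grid.shape, 1.25), years=(2050, 2050),
            mode="anomaly-ratio", grid=grid,
        )
        np.testing.assert_allclose(apply_anomalies(base, anoms).values, 100.0)

    def test_zero_anomaly_reproduces_base(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        for variable, fill, mode in (("tmean", 0.0, "anomaly-difference"),
                                     ("precip", 1.0, "anomaly-ratio")):
            base = self._base(grid, variable, 42.0)
            anoms = MonthlySeries(
                variable, np.full((2, 12) + grid.shape, fill), years=(1961, 1962),
                mode=mode, grid=grid,
            )
            out = apply_anomalies(base, anoms)
            np.testing.assert_allclose(out.values, 42.0)


class TestCloudToSunshine:
    def test_values_and_endpoints(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        vals = np.zeros((12,) + grid.shape)
        vals[0], vals[1], vals[2] = 60.0, 0.0, 100.0
        cloud = ClimatologyField("cloud", vals, grid=grid)
        sun = cloud_to_sunshine(cloud)
        assert sun.variable == "sunshine"
        assert np.all(sun.values[0] == 40.0)
        assert np.all(sun.values[1] == 100.0)
        assert np.all(sun.values[2] == 0.0)

    def test_involution(self, rng):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        vals = rng.uniform(0.0, 100.0, (12,) + grid.shape)
        cloud = ClimatologyField("cloud", vals, grid=grid)
        np.testing.assert_allclose(
            cloud_to_sunshine(cloud_to_sunshine(cloud)).values, vals, atol=1e-12
        )

    def test_out_of_range_raises(self):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        vals = np.full((1, 12) + grid.shape, 50.0)
        vals[0, 3, 0, 0] = 105.0
        series = MonthlySeries("cloud", vals, years=(2000, 2000),
                               mode="anomaly-ratio", grid=grid)
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            cloud_to_sunshine(series)


class TestBuildSpinup:
    def _block(self, trend_per_year=0.0, rng=None):
        grid = build_grid(0.0, 1.0, 0.0, 1.0, 0.5)
        years = np.arange(30.0)
        cycle = 10.0 + 8.0 * np.cos(2 * np.pi * (np.arange(12) - 6.0) / 12.0)
        vals = cycle[None, :, None, None] + trend_per_year * years[:, None, None, None]
        vals = np.broadcast_to(vals, (30, 12) + grid.shape).copy()
        if rng is not None:
            vals += rng.normal(0, 0.2, vals.shape)
        return MonthlySeries("tmean", vals, years=(1901, 1930), grid=grid)

    def test_length_800_years_is_9600_months(self):
        out = build_spinup(self._block(), n_years=800)
        assert out.n_years == 800
        assert out.values.shape[0] * 12 == 9600

    def test_zero_trend_input_reproduced_and_periodic(self):
        block = self._block()
        out = build_spinup(block, n_years=90)
        np.testing.assert_allclose(out.values[:30], block.values, atol=1e-9)
        np.testing.assert_allclose(out.values[30:60], out.values[:30], atol=0)

    def test_linear_trend_removed(self):
        """Post-detrend January slope is < 5% of the imposed slope."""
        b = 0.1  # degC per year
        block = self._block(trend_per_year=b)
        out = build_spinup(block, n_years=30)
        jan = out.values[:, 0, 0, 0]
        slope = np.polyfit(np.arange(30.0), jan, 1)[0]
        assert abs(slope) < 0.05 * b

    def test_wrong_length_input_raises(self):
        block = self._block()
        short = MonthlySeries("tmean", block.values[:20], years=(1901, 1920),
                              grid=block.grid)
        with pytest.raises(ValueError, match="30"):
            build_spinup(short)
        with pytest.raises(ValueError):
            build_spinup(block, n_years=0)


class TestInterpolateSeries:
    def test_constant_series_preserved(self):
        coarse = build_grid(40.0, 44.0, -120.0, -116.0, 0.5)
        fine = build_grid(40.0, 44.0, -120.0, -116.0, 0.5 / 3)
        series = MonthlySeries(
            "tmean", np.full((2, 12) + coarse.shape, 3.25), years=(1961, 1962),
            mode="anomaly-difference", grid=coarse,
        )
        out = interpolate_series(series, fine)
        ok = np.isfinite(out.values)
        assert ok.any()
        np.testing.assert_allclose(out.values[ok], 3.25, atol=1e-12)
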