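"""Bioclimatic indices, PFT screening, water balance, reduced dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from finedgvm.soil import build_soil_column
from finedgvm.vegmodel import (
    DEFAULT_PFTS,
    BioclimIndices,
    PFTParams,
    bioclim_indices,
    screen_pfts,
    simulate_cell,
    simulate_grid,
    thornthwaite_pet,
    water_balance,
)


def _pft(name):
    return next(p for p in DEFAULT_PFTS if p.name == name)


def _const_series(value, ny=30, shape=()):
    return np.full((ny, 12) + shape, float(value))


class TestBioclimIndices:
    def test_constant_ten_degrees(self):
        idx = bioclim_indices(_const_series(10.0))
        assert idx.gdd5 == pytest.approx(365.0 * 5.0)
        assert idx.tc == 10.0 and idx.tw == 10.0

    def test_constant_five_degrees_is_zero(self):
        assert bioclim_indices(_const_series(5.0)).gdd5 == pytest.approx(0.0, abs=1e-9)

    def test_sinusoid_matches_daily_quadrature(self):
        """Pseudo-daily GDD5 within 1% of a 365-step quadrature oracle.

        The oracle rebuilds the stated convention independently: daily
        temperatures linearly interpolated (np.interp, periodic wrap)
        between monthly values anchored at month midpoints, summed over
        a 365-day year.
        """
        lengths = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
        mid = np.cumsum(lengths) - lengths / 2.0
        monthly = 5.0 + 15.0 * np.cos(2 * np.pi * (mid - 196.0) / 365.0)
        days = np.arange(365) + 0.5
        anchors = np.concatenate([[mid[-1] - 365.0], mid, [mid[0] + 365.0]])
        anchor_vals = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
        daily = np.interp(days, anchors, anchor_vals)
        oracle = np.maximum(daily - 5.0, 0.0).sum()
        idx = bioclim_indices(np.broadcast_to(monthly, (30, 12)).copy())
        assert idx.gdd5 == pytest.approx(oracle, rel=0.01)

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="window"):
            bioclim_indices(_const_series(10.0, ny=20))

    def test_year_order_invariance_for_detrended_series(self, rng):
        cycle = 8.0 + 10.0 * np.cos(2 * np.pi * (np.arange(12) - 6.5) / 12.0)
        vals = np.broadcast_to(cycle, (30, 12)).copy()
        vals += rng.normal(0, 0.5, (30, 1))  # year-level offsets only
        idx1 = bioclim_indices(vals)
        perm = rng.permutation(30)
        idx2 = bioclim_indices(vals[perm])
        assert idx1.gdd5 == pytest.approx(idx2.gdd5, rel=1e-12)
        assert idx1.tc == pytest.approx(idx2.tc)


class TestScreenPFTs:
    def test_cold_continental_cell(self):
        names = {p.name for p in screen_pfts(BioclimIndices(1000.0, -25.0, 15.0))}
        assert "temperate needleleaf evergreen" not in names  # tc_min -19.0
        assert "boreal needleleaf evergreen" in names  # -32.5 <= tc <= 0.0, gdd5 >= 600

    def test_warm_cell_tropical_boundary(self):
        names = {p.name for p in screen_pfts(BioclimIndices(4000.0, 16.0, 28.0))}
        assert "temperate broadleaf summergreen" not in names  # tc_max 15.5
        assert "tropical broadleaf evergreen" in names  # tc_min 15.5

    def test_continentality_limit(self):
        # boreal needleleaf summergreen needs tw - tc >= 43
        wide = screen_pfts(BioclimIndices(400.0, -30.0, 14.0))
        narrow = screen_pfts(BioclimIndices(400.0, -30.0, 12.0))
        assert _pft("boreal needleleaf summergreen") in wide
        assert _pft("boreal needleleaf summergreen") not in narrow

    def test_unbounded_params_admit_all(self):
        free = [
            PFTParams(p.name, p.life_form, p.thermal_class, p.leaf_class, p.phenology)
            for p in DEFAULT_PFTS
        ]
        assert len(screen_pfts(BioclimIndices(0.0, -60.0, -60.0), free)) == 10

    def test_impossible_limits_admit_none(self):
        impossible = [
            PFTParams(p.name, p.life_form, p.thermal_class, p.leaf_class,
                      p.phenology, gdd5_min=1e9)
            for p in DEFAULT_PFTS
        ]
        assert screen_pfts(BioclimIndices(5000.0, 10.0, 30.0), impossible) == []

    @given(
        tc=st.floats(-40.0, 15.4),
        tw_offset=st.floats(0.0, 40.0),
        gdd5=st.floats(0.0, 6000.0),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_tropical_pfts_never_survive_cold_winters(self, tc, tw_offset, gdd5):
        survivors = screen_pfts(BioclimIndices(gdd5, tc, tc + tw_offset))
        assert not any(p.thermal_class == "tropical" and p.is_woody for p in survivors)


class TestWaterBalance:
    def test_no_rain_warm_climate_is_zero(self):
        m = water_balance(_const_series(0.0), _const_series(20.0), awc_total=150.0)
        assert m == 0.0

    def test_rain_far_exceeding_demand_is_one(self):
        m = water_balance(_const_series(500.0), _const_series(15.0), awc_total=150.0)
        assert m == pytest.approx(1.0)

    def test_hand_traced_bucket(self):
        """Step-by-step replication of the bucket on a 12-month toy input."""
        tmean = np.array([-2.0, 0.0, 4.0, 8.0, 13.0, 18.0,
                          22.0, 21.0, 15.0, 9.0, 3.0, -1.0])
        precip = np.array([120.0, 90.0, 80.0, 50.0, 30.0, 10.0,
                           5.0, 5.0, 20.0, 60.0, 100.0, 130.0])
        awc = 120.0
        pet = thornthwaite_pet(tmean)  # shared deterministic demand input

        # independent spreadsheet-style trace of the documented update rule
        store = awc
        for _ in range(200):  # to periodic steady state
            for m in range(12):
                avail = store + precip[m]
                aet = min(pet[m], avail)
                store = min(awc, avail - aet)
        aet_sum = 0.0
        for m in range(12):
            avail = store + precip[m]
            aet = min(pet[m], avail)
            store = min(awc, avail - aet)
            aet_sum += aet
        expected = aet_sum / pet.sum()

        got = water_balance(
            np.broadcast_to(precip, (30, 12)).copy(),
            np.broadcast_to(tmean, (30, 12)).copy(),
            awc,
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_negative_precip_raises(self):
        with pytest.raises(ValueError):
            water_balance(_const_series(-1.0), _const_series(10.0), 100.0)

    def test_zero_pet_all_year_is_one(self):
        m = water_balance(_const_series(0.0), _const_series(-10.0), 100.0)
        assert m == 1.0


class TestSimulateCell:
    def _climate(self, tmean, precip):
        return {"tmean": _const_series(tmean), "precip": _const_series(precip)}

    def _soil(self):
        return build_soil_column(sand=45.0, clay=20.0)

    def test_empty_surviving_set_gives_zero_cover(self):
        """No survivors (impossible limits) -> a barren-classifiable cell."""
        impossible = [
            PFTParams(p.name, p.life_form, p.thermal_class, p.leaf_class,
                      p.phenology, gdd5_min=1e9)
            for p in DEFAULT_PFTS
        ]
        climate = self._climate(12.0, 60.0)
        cell = simulate_cell(climate, self._soil(), params=impossible)
        assert cell.total_fpc == 0.0
        assert cell.fire_return_interval > 0

    def test_frozen_cell_is_near_barren_under_default_limits(self):
        # gdd5 = 0 and tc = -40: only the unbounded herbs survive, and
        # zero productivity keeps their cover at zero
        cycle = -40.0 + 20.0 * np.cos(2 * np.pi * (np.arange(12) - 6.0) / 12.0)
        climate = {
            "tmean": np.broadcast_to(cycle, (30, 12)).copy(),
            "precip": _const_series(50.0),
        }
        cell = simulate_cell(climate, self._soil())
        assert cell.total_fpc < 0.01

    def test_co2_never_decreases_woody_cover(self):
        climate = self._climate(12.0, 60.0)
        lo = simulate_cell(climate, self._soil(), co2_ppm=368.0)
        hi = simulate_cell(climate, self._soil(), co2_ppm=734.0)
        woody = np.array([p.is_woody for p in DEFAULT_PFTS])
        assert np.all(hi.fpc[woody] >= lo.fpc[woody] - 1e-12)

    def test_wetter_cell_grows_more_trees(self):
        dry = simulate_cell(self._climate(14.0, 20.0), self._soil())
        wet = simulate_cell(self._climate(14.0, 80.0), self._soil())
        assert wet.moisture_index > dry.moisture_index
        assert wet.woody_fpc() > dry.woody_fpc()

    def test_summary_invariants_over_random_sweep(self, rng):
        """Sum FPC <= 1 and FRI > 0 across 1000 random climate cells."""
        n = 1000
        base = rng.uniform(-15.0, 25.0, n)
        amp = rng.uniform(0.0, 20.0, n)
        cycle = np.cos(2 * np.pi * (np.arange(12) - 6.0) / 12.0)
        tmean = np.broadcast_to(
            base + amp * cycle[:, None], (30, 12, n)
        ).copy()
        precip = rng.uniform(0.0, 200.0, (30, 12, n))
        awc = rng.uniform(50.0, 300.0, n)
        out = simulate_grid(tmean, precip, awc, co2_ppm=500.0)
        assert np.all(out["fpc"].sum(axis=0) <= 1.0 + 1e-9)
        assert np.all(out["fpc"] >= 0.0)
        assert np.all(out["fire_return_interval"] > 0.0)
        assert np.all(out["height"] >= 0.0)
        assert np.all((out["moisture_index"] >= 0) & (out["moisture_index"] <= 1))

    def test_grid_and_cell_paths_agree(self):
        climate = self._climate(10.0, 70.0)
        cell = simulate_cell(climate, self._soil(), co2_ppm=420.0)
        grid_out = simulate_grid(
            climate["tmean"][:, :, None],
            climate["precip"][:, :, None],
            np.array([self._soil().awc_total]),
            co2_ppm=420.0,
        )
        np.testing.assert_allclose(grid_out["fpc"][:, 0], cell.fpc)
        np.testing.assert_allclose(
            grid_out["fire_return_interval"][0], cell.fire_return_interval
        )
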