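"""Summary products: curves, climate-space bins, monthly memory, regions."""

import numpy as np
import pytest

from vegmem.grid import BiomeMap
from vegmem.metrics import r_squared
from vegmem.permute import FULL
from vegmem.preprocess import decompose
from vegmem.summaries import (climate_space, memory_curve, monthly_memory,
                              regional_example)

from conftest import make_cube


class TestMemoryCurve:
    def _biomes(self, n):
        return BiomeMap(np.zeros(n, int), np.zeros(n))

    def test_baseline_only_zero_curve(self, rng):
        r2 = {0: rng.random(5)}
        df = memory_curve(r2, self._biomes(5))
        np.testing.assert_allclose(df.mem_mean, 0.0)

    def test_full_equals_headline(self, rng):
        r2 = {0: rng.random(5), FULL: rng.random(5)}
        df = memory_curve(r2, self._biomes(5))
        g = df[(df.scope == "global") & (df.model == "M_full")]
        assert g.mem_mean.iloc[0] == pytest.approx(
            (r2[FULL] - r2[0]).mean())

    def test_missing_baseline_error(self, rng):
        with pytest.raises(ValueError, match="baseline"):
            memory_curve({1: rng.random(3)}, self._biomes(3))

    def test_iqr_ordering(self, rng):
        r2 = {0: np.zeros(50), 2: rng.random(50)}
        df = memory_curve(r2, self._biomes(50))
        row = df[df.model == "M_2"].iloc[0]
        assert row.mem_q1 <= row.mem_mean + 1e-12
        assert row.mem_q1 <= row.mem_q3


class TestClimateSpace:
    def test_min_count_masking(self):
        mem9 = np.ones(9)
        grid = climate_space(mem9, np.full(9, 10.0), np.full(9, 100.0),
                             [0, 20], [0, 200], min_count=10)
        assert grid.masked[0, 0]
        grid10 = climate_space(np.ones(10), np.full(10, 10.0),
                               np.full(10, 100.0), [0, 20], [0, 200])
        assert not grid10.masked[0, 0]
        assert grid10.mean_mem[0, 0] == pytest.approx(1.0)

    def test_counts_sum_to_binned_pixels(self, rng):
        mem = rng.normal(size=40)
        t = rng.uniform(0, 30, 40)
        p = rng.uniform(0, 1000, 40)
        grid = climate_space(mem, t, p, np.arange(0, 31, 5),
                             np.arange(0, 1001, 250))
        assert grid.count.sum() == 40

    def test_single_cell_global_mean(self, rng):
        mem = rng.normal(size=20)
        grid = climate_space(mem, np.full(20, 5.0), np.full(20, 50.0),
                             [0, 10], [0, 100])
        assert grid.mean_mem[0, 0] == pytest.approx(mem.mean())

    def test_bad_edges(self):
        with pytest.raises(ValueError):
            climate_space(np.ones(3), np.ones(3), np.ones(3), [1, 0], [0, 1])


def _seasonal_cube(rng, years=3, spy=4, n_pix=12, lat_sign=1):
    steps = years * spy
    season = np.sin(2 * np.pi * np.arange(steps) / spy)
    vals = (season[None, :] + 0.3 * rng.normal(size=(n_pix, steps))
            + np.linspace(0, 1, n_pix)[:, None])
    lat = np.full(n_pix, 20.0 * lat_sign)
    return make_cube(vals, steps_per_year=spy, lat=lat)


class TestMonthlyMemory:
    def test_perfect_predictions_zero(self, rng):
        cube = _seasonal_cube(rng, spy=24)
        bm = BiomeMap(np.zeros(cube.n_pixels, int), cube.lat)
        df = monthly_memory(cube, cube.values, cube.values, bm)
        np.testing.assert_allclose(df.mem, 0.0, atol=1e-12)

    def test_climatology_vs_truth_toy(self, rng):
        """pred_0 = seasonal climatology, pred_full = truth: the monthly gain
        equals 1 - R2(climatology) computed directly."""
        cube = _seasonal_cube(rng, years=4, spy=24, n_pix=10)
        dec = decompose(cube)
        msc_tiled = dec.msc_tiled()
        bm = BiomeMap(np.zeros(cube.n_pixels, int), cube.lat)
        df = monthly_memory(cube, cube.values, msc_tiled, bm)
        # direct computation on the aggregated series for month 1
        w = cube.area_weights()
        so = (cube.values * w[:, None]).sum(0) / w.sum()
        sm = (msc_tiled * w[:, None]).sum(0) / w.sum()
        months = cube.time.months()
        expect = 1.0 - r_squared(so[months == 1], sm[months == 1])
        got = df[(df.month == 1)].mem.iloc[0]
        assert got == pytest.approx(expect, abs=1e-9)

    def test_hemisphere_split(self, rng):
        north = _seasonal_cube(rng, lat_sign=1)
        bm = BiomeMap(np.zeros(north.n_pixels, int), north.lat)
        df = monthly_memory(north, north.values, north.values, bm,
                            min_pixels=1)
        assert set(df.hemisphere) == {"N"}

    def test_min_pixels_suppression(self, rng):
        cube = _seasonal_cube(rng, n_pix=5)
        bm = BiomeMap(np.zeros(5, int), cube.lat)
        df = monthly_memory(cube, cube.values, cube.values, bm, min_pixels=10)
        assert df.empty

    def test_needs_two_years(self, rng):
        cube = _seasonal_cube(rng, years=1)
        bm = BiomeMap(np.zeros(cube.n_pixels, int), cube.lat)
        with pytest.raises(ValueError):
            monthly_memory(cube, cube.values, cube.values, bm)


class TestRegionalExample:
    def test_perfect_prediction_zero_error(self, rng):
        cube = _seasonal_cube(rng)
        df = regional_example(cube, {"M_full": cube.values},
                              (-90, 90, -180, 180))
        np.testing.assert_allclose(df.abs_err_mean_M_full, 0.0)

    def test_single_pixel_zero_std(self, rng):
        cube = make_cube(rng.normal(size=(1, 8)), steps_per_year=4)
        df = regional_example(cube, {"m": cube.values + 1.0},
                              (-90, 90, -180, 180))
        np.testing.assert_allclose(df.abs_err_std_m, 0.0)
        np.testing.assert_allclose(df.abs_err_mean_m, 1.0)

    def test_two_pixel_mean_and_population_std(self):
        cube = make_cube(np.zeros((2, 4)), steps_per_year=4, lat=[0.0, 0.0])
        pred = np.stack([np.zeros(4), 2.0 * np.ones(4)])
        df = regional_example(cube, {"m": pred}, (-90, 90, -180, 180))
        np.testing.assert_allclose(df.abs_err_mean_m, 1.0)
        np.testing.assert_allclose(df.abs_err_std_m, 1.0)

    def test_empty_region(self, rng):
        cube = _seasonal_cube(rng)
        with pytest.raises(ValueError, match="empty"):
            regional_example(cube, {}, (80, 90, 0, 1))


class TestHemisphereContrast:
    def test_monthly_peaks_in_opposite_halves(self, rng):
        """When interannual anomalies are concentrated in the local summer
        (phase flipped across hemispheres), the months where temporal context
        helps most fall in opposite calendar halves."""
        years, spy, n_pix = 6, 24, 20
        steps = years * spy
        frac = (np.arange(steps) % spy) / spy
        lat = np.where(np.arange(n_pix) < n_pix // 2, 30.0, -30.0)
        season = np.sin(2 * np.pi * (frac[None, :] - 0.25
                                     - 0.5 * (lat[:, None] < 0)))
        envelope = np.clip(season, 0.0, None)  # active in local summer only
        year_effect = np.repeat(rng.normal(size=(n_pix, years)), spy, axis=1)
        obs = season + envelope * year_effect + 0.01 * rng.normal(
            size=(n_pix, steps))
        cube = make_cube(obs, steps_per_year=spy, lat=lat)
        dec = decompose(cube)
        bm = BiomeMap(np.zeros(n_pix, int), lat)
        # oracle predictions: climatology (no interannual skill) vs truth
        df = monthly_memory(cube, cube.values, dec.msc_tiled(), bm,
                            min_pixels=5)
        peaks = {h: df[df.hemisphere == h].set_index("month").mem.idxmax()
                 for h in ("N", "S")}
        sep = abs(peaks["N"] - peaks["S"])
        assert min(sep, 12 - sep) >= 4
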