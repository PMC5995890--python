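"""Bespoke climate statistics, edaphic aggregation, TRI and hindcasting."""

import numpy as np
import pandas as pd
import pytest

from woodycover.covariates import (
    depth_weighted_soil,
    extreme_rainfall_counts,
    fit_hindcast,
    mean_and_trend,
    precipitation_concentration_index,
    rainfall_variability,
    terrain_ruggedness,
)


class TestMeanAndTrend:
    def test_constant_series(self):
        m, s = mean_and_trend(np.full((4, 2), 7.0), np.arange(4.0))
        np.testing.assert_allclose(m, 7.0)
        np.testing.assert_allclose(s, 0.0, atol=1e-13)

    def test_linear_series(self):
        m, s = mean_and_trend(np.array([10.0, 12.0, 14.0])[:, None], np.arange(3.0))
        np.testing.assert_allclose(m, 12.0)
        np.testing.assert_allclose(s, 2.0)

    def test_random_series_matches_oracle(self):
        rng = np.random.default_rng(3)
        x = np.arange(8.0)
        y = rng.normal(0, 1, (8, 5))
        _, s = mean_and_trend(y, x)
        for j in range(5):
            xb = x.mean()
            want = np.sum((x - xb) * (y[:, j] - y[:, j].mean())) / np.sum((x - xb) ** 2)
            np.testing.assert_allclose(s[j], want, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mean_and_trend(np.ones((1, 2)), np.zeros(1))


class TestExtremeRainfall:
    def test_constant_rainfall_zero_counts(self):
        """All 5-day sums equal the threshold; strict exceedance counts 0."""
        days = 365 * 3
        years = np.repeat([2000, 2001, 2002], 365)
        res = extreme_rainfall_counts(np.full((days, 1), 2.0), years)
        assert (res.counts == 0).all()

    def test_single_storm_attributed_to_its_year(self):
        days = 365 * 10
        years = np.repeat(np.arange(2000, 2010), 365)
        daily = np.full((days, 1), 1.0)  # flat background: all sums at threshold
        daily[365 * 4 + 100 : 365 * 4 + 105, 0] = 200.0  # one 5-day storm in 2004
        res = extreme_rainfall_counts(daily, years)
        i2004 = list(res.years).index(2004)
        assert res.counts[i2004, 0] >= 1
        other = np.delete(res.counts[:, 0], i2004)
        assert (other == 0).all()

    def test_sliding_window_oracle_365_days(self):
        """365 daily values admit 361 sliding 5-day windows; threshold and
        counts match a naive loop oracle."""
        rng = np.random.default_rng(1)
        daily = rng.uniform(0, 1, (365, 1))
        years = np.full(365, 2000)
        res = extreme_rainfall_counts(daily, years)
        sums = np.array([daily[i : i + 5, 0].sum() for i in range(361)])
        assert sums.shape[0] == 361
        thr = np.percentile(sums, 95)
        np.testing.assert_allclose(res.threshold[0], thr, atol=1e-10)
        assert res.counts[0, 0] == int((sums > thr).sum())

    def test_threshold_depends_on_full_record(self):
        """Appending a wet year can change earlier years' counts."""
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 1, (365 * 3, 1))
        years3 = np.repeat([0, 1, 2], 365)
        res3 = extreme_rainfall_counts(base, years3)
        wet = np.vstack([base, np.full((365, 1), 50.0)])
        years4 = np.concatenate([years3, np.full(365, 3)])
        res4 = extreme_rainfall_counts(wet, years4)
        # wet year raises the 95th-percentile threshold: earlier counts shrink
        assert res4.counts[:3, 0].sum() < res3.counts[:, 0].sum()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            extreme_rainfall_counts(np.ones((3, 1)), np.zeros(3))


class TestPCI:
    def test_uniform_months_lower_bound(self):
        np.testing.assert_allclose(precipitation_concentration_index(np.full((12, 1), 50.0)), 100.0 / 12.0)

    def test_single_month_upper_bound(self):
        p = np.zeros((12, 1))
        p[3] = 123.0
        np.testing.assert_allclose(precipitation_concentration_index(p), 100.0)

    def test_worked_example(self):
        months = np.array([100.0, 50.0, 50.0] + [0.0] * 9)[:, None]
        np.testing.assert_allclose(precipitation_concentration_index(months), 37.5)

    def test_zero_rainfall_missing(self):
        assert np.isnan(precipitation_concentration_index(np.zeros((12, 1))))[0]

    def test_multi_year_reduced_to_mean_months(self):
        rng = np.random.default_rng(7)
        years = rng.uniform(0, 100, (5, 12, 1))
        a = precipitation_concentration_index(years)
        b = precipitation_concentration_index(years.mean(axis=0))
        np.testing.assert_allclose(a, b)

    def test_bounds_property_1000_vectors(self):
        rng = np.random.default_rng(99)
        months = rng.uniform(0.0, 500.0, (12, 1000)) * (rng.random((12, 1000)) < 0.7)
        pci = precipitation_concentration_index(months)
        ok = ~np.isnan(pci)
        assert (pci[ok] >= 100.0 / 12.0 - 1e-9).all()
        assert (pci[ok] <= 100.0 + 1e-9).all()


class TestRainfallVariability:
    def test_constant_series_zero_sd(self):
        years = np.repeat([0, 1], 8)
        sd_a, sd_o = rainfall_variability(np.full((16, 1), 2.0), years)
        np.testing.assert_allclose(sd_a, 0.0)
        np.testing.assert_allclose(sd_o, 0.0)

    def test_two_point_annual_sd(self):
        """Annual totals {900, 1100} have population SD 100."""
        obs = np.concatenate([np.full(9, 100.0), np.full(11, 100.0)])[:, None]
        years = np.concatenate([np.zeros(9, int), np.ones(11, int)])
        sd_a, _ = rainfall_variability(obs, years)
        np.testing.assert_allclose(sd_a, 100.0)

    def test_matches_textbook_sd(self):
        rng = np.random.default_rng(1)
        obs = rng.exponential(2.0, (40, 3))
        years = np.repeat([0, 1, 2, 3], 10)
        sd_a, sd_o = rainfall_variability(obs, years)
        totals = np.stack([obs[years == y].sum(axis=0) for y in range(4)])
        np.testing.assert_allclose(sd_a, totals.std(axis=0), atol=1e-12)
        np.testing.assert_allclose(sd_o, obs.std(axis=0), atol=1e-12)


class TestDepthWeightedSoil:
    def test_equal_layers(self):
        iv = [(0, 5), (5, 15), (15, 30)]
        np.testing.assert_allclose(depth_weighted_soil(np.full((3, 2), 4.2), iv), 4.2)

    def test_two_layer_arithmetic(self):
        out = depth_weighted_soil(np.array([10.0, 20.0])[:, None], [(0, 5), (5, 20)])
        np.testing.assert_allclose(out, 17.5)

    def test_six_layer_profile_matches_loop(self):
        rng = np.random.default_rng(12)
        iv = [(0, 5), (5, 15), (15, 30), (30, 60), (60, 100), (100, 200)]
        vals = rng.uniform(0, 30, (6, 4))
        out = depth_weighted_soil(vals, iv)
        th = np.array([b - a for a, b in iv], dtype=float)
        want = sum(vals[i] * th[i] for i in range(6)) / th.sum()
        np.testing.assert_allclose(out, want, atol=1e-12)
        assert (out >= vals.min(axis=0) - 1e-12).all()
        assert (out <= vals.max(axis=0) + 1e-12).all()

    def test_bad_intervals_rejected(self):
        with pytest.raises(ValueError):
            depth_weighted_soil(np.ones((2, 1)), [(0, 5), (7, 10)])
        with pytest.raises(ValueError):
            depth_weighted_soil(np.ones((2, 1)), [(0, 5), (5, 5)])


class TestTRI:
    def test_flat_dem_zero(self):
        np.testing.assert_allclose(terrain_ruggedness(np.full((5, 5), 100.0)), 0.0)

    def test_single_neighbor_difference(self):
        dem = np.full((3, 3), 10.0)
        dem[0, 0] = 13.0
        assert terrain_ruggedness(dem, "riley")[1, 1] == pytest.approx(3.0)
        assert terrain_ruggedness(dem, "sum_abs")[1, 1] == pytest.approx(3.0)

    @pytest.mark.parametrize("method", ["riley", "sum_abs"])
    def test_random_dem_matches_neighbor_loop(self, method):
        rng = np.random.default_rng(8)
        dem = rng.uniform(0, 100, (5, 5))
        tri = terrain_ruggedness(dem, method)
        for i in range(5):
            for j in range(5):
                acc = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 5 and 0 <= jj < 5:
                            d = dem[i, j] - dem[ii, jj]
                            acc += d * d if method == "riley" else abs(d)
                want = np.sqrt(acc) if method == "riley" else acc
                np.testing.assert_allclose(tri[i, j], want, atol=1e-10)

    def test_invariant_under_constant_offset(self):
        rng = np.random.default_rng(9)
        dem = rng.uniform(0, 50, (6, 6))
        np.testing.assert_allclose(terrain_ruggedness(dem), terrain_ruggedness(dem + 1000.0), atol=1e-9)
        assert (terrain_ruggedness(dem) >= 0).all()


class TestHindcast:
    @staticmethod
    def _world(seed=0, n=300):
        rng = np.random.default_rng(seed)
        preds, truth = {}, {}
        for e in range(4):
            x = pd.DataFrame({"pop": rng.uniform(0, 10, n), "lon": rng.uniform(0, 5, n)})
            preds[e] = x
            truth[e] = 3.0 * x["pop"].to_numpy() + 0.5 * x["lon"].to_numpy()
        return preds, truth

    def test_noiseless_cross_epoch_validation(self):
        from woodycover.brt import BRTParams

        preds, truth = self._world()
        params = BRTParams(learning_rate=0.1, cv_folds=5, max_trees=300, seed=1)
        hm = fit_hindcast(
            truth[1],
            preds,
            {e: 1990.0 + 5 * e for e in preds},
            params=params,
            reference_epoch=1,
            validation_responses=truth,
        )
        assert all(r2 >= 0.95 for r2 in hm.validation_r2.values())
        np.testing.assert_allclose(hm.contributions.sum(), 100.0, atol=1e-6)

    def test_constant_predictors_constant_series(self):
        from woodycover.brt import BRTParams

        rng = np.random.default_rng(1)
        n = 120
        x0 = pd.DataFrame({"pop": rng.uniform(0, 10, n), "lon": rng.uniform(0, 5, n)})
        preds = {e: x0.copy() for e in range(3)}
        resp = 2.0 * x0["pop"].to_numpy()
        params = BRTParams(learning_rate=0.1, cv_folds=4, max_trees=150, seed=2)
        hm = fit_hindcast(resp, preds, {e: 2000.0 + 5 * e for e in preds}, params=params)
        np.testing.assert_allclose(hm.trend, 0.0, atol=1e-10)

    def test_determinism(self):
        from woodycover.brt import BRTParams

        preds, truth = self._world(seed=5, n=150)
        params = BRTParams(learning_rate=0.1, cv_folds=4, max_trees=100, seed=3)
        a = fit_hindcast(truth[0], preds, {e: 2000.0 + 5 * e for e in preds}, params=params)
        b = fit_hindcast(truth[0], preds, {e: 2000.0 + 5 * e for e in preds}, params=params)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_missing_epoch_midpoint_rejected(self):
        preds, truth = self._world(n=50)
        with pytest.raises(ValueError, match="midpoint"):
            fit_hindcast(truth[0], preds, {0: 2000.0})
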