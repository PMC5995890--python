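"""Boosted-regression-tree attribution: aggregation, collinearity, fitting,
importance, simplification, partial dependence and the permutation check.

Unit-level fits use a faster parameterization (higher learning rate, fewer
trees/folds) than the headline configuration; the headline parameters are
exercised in the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

from woodycover.brt import (
    BRTParams,
    aggregate_to_grid,
    collinearity_filter,
    fit_brt,
    partial_dependence,
    permutation_sanity,
    relative_importance,
    simplify_model,
)

FAST = dict(learning_rate=0.1, cv_folds=5, max_trees=200, min_trees=5)


def _signal_table(n=400, seed=0, noise=0.2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{i}": rng.standard_normal(n) for i in range(4)})
    y = 2.0 * X["x0"].to_numpy() + noise * rng.standard_normal(n)
    return X, y


class TestAggregateToGrid:
    def test_uniform_raster_both_rules(self):
        r = np.full((8, 8), 3.3)
        np.testing.assert_allclose(aggregate_to_grid(r, 30.0, 120.0), 3.3)   # mean rule
        np.testing.assert_allclose(aggregate_to_grid(r, 1000.0, 2000.0), 3.3)  # bilinear rule

    def test_mean_with_missing(self):
        r = np.array([[1.0, 2.0], [3.0, np.nan]])
        np.testing.assert_allclose(aggregate_to_grid(r, 30.0, 60.0), [[2.0]])

    def test_empty_cell_missing(self):
        r = np.full((2, 2), np.nan)
        assert np.isnan(aggregate_to_grid(r, 30.0, 60.0)).all()

    def test_bilinear_ramp_matches_analytic(self):
        """Bilinear resampling of a linear ramp returns the ramp at centroids."""
        res, cell = 1000.0, 2000.0
        n = 12
        i = np.arange(n)
        ramp = 2.0 * i[:, None] + 3.0 * i[None, :]  # linear in pixel indices
        out = aggregate_to_grid(ramp, res, cell)
        ci = (np.arange(n // 2) + 0.5) * cell / res - 0.5
        want = 2.0 * ci[:, None] + 3.0 * ci[None, :]
        np.testing.assert_allclose(out, want, atol=1e-9)

    def test_resolution_dispatch_at_cutoff(self):
        """<=500 m reduces to block means; >500 m samples bilinearly.

        On a quadratic row profile (factor 4) the two rules disagree, so the
        dispatch at the 500 m boundary is observable.
        """
        i = np.arange(8.0)
        r = np.broadcast_to((i**2)[:, None], (8, 8)).copy()
        mean = aggregate_to_grid(r, 500.0, 2000.0)
        np.testing.assert_allclose(mean[:, 0], [(0 + 1 + 4 + 9) / 4, (16 + 25 + 36 + 49) / 4])
        bil = aggregate_to_grid(r, 500.0001, 2000.0004)
        np.testing.assert_allclose(bil[:, 0], [(1 + 4) / 2, (25 + 36) / 2])  # rows 1.5 and 5.5

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            aggregate_to_grid(np.ones((4, 4)), -1.0, 100.0)


class TestCollinearityFilter:
    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.standard_normal(100)})
        df["b"] = df["a"]
        red, rep = collinearity_filter(df)
        assert len(rep["removed"]) == 1
        assert set(red.columns) == {"a", "b"} - set(rep["removed"])

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({k: rng.standard_normal(500) for k in "abc"})
        red, rep = collinearity_filter(df)
        assert rep["removed"] == []
        assert list(red.columns) == ["a", "b", "c"]

    def test_transitive_closure_chain(self):
        """A~B, B~C strong, A~C weak: one group {A,B,C}, two removed."""
        cov = np.array([[1.0, 0.8, 0.3], [0.8, 1.0, 0.8], [0.3, 0.8, 1.0]])
        rng = np.random.default_rng(2)
        X = rng.multivariate_normal(np.zeros(3), cov, size=3000)
        df = pd.DataFrame(X, columns=["A", "B", "C"])
        red, rep = collinearity_filter(df, threshold=0.7, priority=["B"])
        assert len(rep["groups"]) == 1
        assert sorted(rep["groups"][0]["members"]) == ["A", "B", "C"]
        assert rep["groups"][0]["kept"] == "B"
        assert sorted(rep["removed"]) == ["A", "C"]

    def test_constant_column_warned_not_grouped(self):
        df = pd.DataFrame({"a": np.arange(50.0), "c": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            red, rep = collinearity_filter(df)
        assert rep["removed"] == []


class TestFitBRT:
    def test_pure_noise_low_deviance_explained(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({f"x{i}": rng.standard_normal(500) for i in range(10)})
        y = rng.standard_normal(500)
        m = fit_brt(X, y, None, BRTParams(seed=3, **FAST))
        assert m.cv_deviance_explained <= 0.05

    def test_strong_signal_recovered(self):
        X, y = _signal_table(noise=0.1)
        m = fit_brt(X, y, None, BRTParams(seed=4, **FAST))
        assert m.cv_deviance_explained >= 0.8
        assert m.importances.idxmax() == "x0"

    def test_weight_scale_invariance(self):
        X, y = _signal_table(seed=5)
        w = np.random.default_rng(5).uniform(0.5, 2.0, len(y))
        a = fit_brt(X, y, w, BRTParams(seed=6, **FAST))
        b = fit_brt(X, y, 2.0 * w, BRTParams(seed=6, **FAST))
        assert a.best_trees == b.best_trees
        np.testing.assert_allclose(a.cv_deviance_explained, b.cv_deviance_explained, atol=1e-9)
        np.testing.assert_allclose(a.predict(X), b.predict(X), atol=1e-9)

    def test_determinism(self):
        X, y = _signal_table(seed=7)
        a = fit_brt(X, y, None, BRTParams(seed=8, **FAST))
        b = fit_brt(X, y, None, BRTParams(seed=8, **FAST))
        assert a.best_trees == b.best_trees
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_input_validation(self):
        X, y = _signal_table(n=8)
        with pytest.raises(ValueError, match="folds"):
            fit_brt(X, y, None, BRTParams(cv_folds=10, **{k: v for k, v in FAST.items() if k != "cv_folds"}))
        with pytest.raises(ValueError, match="constant"):
            fit_brt(X.head(50), np.ones(50), None, BRTParams(seed=0, **FAST))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            BRTParams(learning_rate=0.0)
        with pytest.raises(ValueError):
            BRTParams(bag_fraction=1.5)
        with pytest.raises(ValueError):
            BRTParams(family="poisson")


class TestRelativeImportance:
    def test_sums_to_100(self):
        X, y = _signal_table(seed=9)
        m = fit_brt(X, y, None, BRTParams(seed=9, **FAST))
        np.testing.assert_allclose(m.importances.sum(), 100.0, atol=1e-6)

    def test_single_predictor_full_importance(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"only": rng.standard_normal(200)})
        y = X["only"].to_numpy() + 0.1 * rng.standard_normal(200)
        m = fit_brt(X, y, None, BRTParams(seed=10, **FAST))
        np.testing.assert_allclose(m.importances["only"], 100.0)

    def test_never_selected_zero(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x": rng.standard_normal(200), "const": np.zeros(200)})
        y = X["x"].to_numpy()
        m = fit_brt(X, y, None, BRTParams(seed=11, **FAST))
        assert m.importances["const"] == 0.0

    def test_variance_ratio_ordering(self):
        """4:1 variance contributions give an importance ratio in [2, 8]."""
        rng = np.random.default_rng(12)
        n = 600
        X = pd.DataFrame({"big": rng.standard_normal(n), "small": rng.standard_normal(n)})
        y = 2.0 * X["big"].to_numpy() + 1.0 * X["small"].to_numpy() + 0.1 * rng.standard_normal(n)
        m = fit_brt(X, y, None, BRTParams(seed=12, **FAST))
        ratio = m.importances["big"] / m.importances["small"]
        assert 2.0 <= ratio <= 8.0


class TestSimplify:
    def test_noise_predictors_eliminated(self):
        rng = np.random.default_rng(13)
        n = 500
        cols = {f"inf{i}": rng.standard_normal(n) for i in range(3)}
        cols.update({f"noise{i}": rng.standard_normal(n) for i in range(3)})
        X = pd.DataFrame(cols)
        y = sum((1.0 + 0.3 * i) * X[f"inf{i}"].to_numpy() for i in range(3))
        y = y + 0.15 * rng.standard_normal(n)
        params = BRTParams(seed=13, **FAST)
        m = fit_brt(X, y, None, params)
        red, trace = simplify_model(m, X, y, None, params)
        assert set(red.features) == {"inf0", "inf1", "inf2"}
        assert {s.dropped for s in trace} == {"noise0", "noise1", "noise2"}

    def test_all_informative_minimal_drops(self):
        rng = np.random.default_rng(14)
        n = 500
        X = pd.DataFrame({f"x{i}": rng.standard_normal(n) for i in range(3)})
        y = sum(1.0 * X[f"x{i}"].to_numpy() for i in range(3)) + 0.1 * rng.standard_normal(n)
        params = BRTParams(seed=14, **FAST)
        m = fit_brt(X, y, None, params)
        red, trace = simplify_model(m, X, y, None, params)
        assert len(red.features) == 3

    def test_single_variable_unchanged(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame({"x": rng.standard_normal(200)})
        y = X["x"].to_numpy() + 0.1 * rng.standard_normal(200)
        m = fit_brt(X, y, None, BRTParams(seed=15, **FAST))
        red, trace = simplify_model(m, X, y, None)
        assert red.features == ["x"] and trace == []


class TestPartialDependence:
    def test_zero_importance_flat(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame({"x": rng.standard_normal(300), "dead": np.zeros(300)})
        y = X["x"].to_numpy()
        m = fit_brt(X, y, None, BRTParams(seed=16, **FAST))
        pd_ = partial_dependence(m, X, "dead")
        assert pd_.response.max() - pd_.response.min() <= 0.01 * (y.max() - y.min())

    def test_monotone_for_identity_response(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 400), "z": rng.standard_normal(400)})
        y = X["x"].to_numpy()
        m = fit_brt(X, y, None, BRTParams(seed=17, **FAST))
        pd_ = partial_dependence(m, X, "x", n_points=15)
        assert np.all(np.diff(pd_.response) >= -1e-6)
        assert pd_.slope() > 0

    def test_matches_brute_force_loop(self):
        X, y = _signal_table(seed=18, n=200)
        m = fit_brt(X, y, None, BRTParams(seed=18, **FAST))
        pd_ = partial_dependence(m, X, "x0", n_points=3)
        for gi, g in enumerate(pd_.grid):
            rows = X.copy()
            acc = 0.0
            for k in range(len(rows)):
                row = rows.iloc[[k]].copy()
                row["x0"] = g
                acc += m.predict(row)[0]
            np.testing.assert_allclose(pd_.response[gi], acc / len(rows), atol=1e-10)

    def test_grid_clipped_to_5_95(self):
        X, y = _signal_table(seed=19)
        m = fit_brt(X, y, None, BRTParams(seed=19, **FAST))
        pd_ = partial_dependence(m, X, "x1")
        lo, hi = np.percentile(X["x1"], [5, 95])
        assert pd_.grid[0] == pytest.approx(lo) and pd_.grid[-1] == pytest.approx(hi)
        assert np.all(np.diff(pd_.grid) > 0)

    def test_unknown_variable_rejected(self):
        X, y = _signal_table(seed=20, n=100)
        m = fit_brt(X, y, None, BRTParams(seed=20, **FAST))
        with pytest.raises(KeyError):
            partial_dependence(m, X, "ghost")


class TestModelFamilies:
    def test_combined_at_least_driver_only(self):
        """With informative facilitators present, the combined model explains
        at least as much CV deviance as the driver-only model."""
        from woodycover.synthetic import generate_driver_table

        table, truth = generate_driver_table(n_cells=400, seed=30, include_facilitators=True)
        data = table.data
        y = data[truth["response"]].to_numpy()
        w = data[truth["weight"]].to_numpy()
        params = BRTParams(seed=30, **FAST)
        drivers = table.variables("driver")
        combined = fit_brt(data[table.variables()], y, w, params, family_tag="combined")
        driver_only = fit_brt(data[drivers], y, w, params, family_tag="driver")
        assert combined.cv_deviance_explained >= driver_only.cv_deviance_explained


class TestPermutationSanity:
    def test_permutation_destroys_signal_both_seeds(self):
        X, y = _signal_table(seed=21, noise=0.1)
        params = BRTParams(seed=21, **FAST)
        results = permutation_sanity(X, y, None, params, seeds=(0, 1))
        assert len(results) == 2
        assert all(r.failed_to_resolve for r in results)
        assert all(r.cv_deviance_explained <= 0.05 for r in results)

    def test_unpermuted_contrast(self):
        X, y = _signal_table(seed=22, noise=0.1)
        params = BRTParams(seed=22, **FAST)
        m = fit_brt(X, y, None, params)
        perm = permutation_sanity(X, y, None, params, seeds=(3,))[0]
        assert m.cv_deviance_explained >= 0.8
        assert perm.cv_deviance_explained < m.cv_deviance_explained
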