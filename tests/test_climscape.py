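"""RDA fitting, forward selection, adaptive indices, and offsets."""

import numpy as np
import pandas as pd
import pytest

from ploidsv import climscape
from ploidsv.climscape import (
    adaptive_index,
    climatic_distance,
    ezekiel_adj_r2,
    fit_rda,
    forward_select,
    future_offset,
    geo_pcoa,
    grid_occupancy,
    partial_rda_decomposition,
)
from ploidsv.popgen import haversine_km


def _env(n, k=4, seed=0, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"v{i + 1}" for i in range(k)]
    return pd.DataFrame(rng.normal(size=(n, k)), columns=names)


class TestFitRda:
    def test_exact_linear_response_r2_one(self):
        X = _env(20, 3, seed=1)
        Y = np.outer(X["v1"], np.linspace(-1, 1, 15))
        model = fit_rda(Y, X)
        assert model.r2 == pytest.approx(1.0, abs=1e-9)
        assert model.eigenvalues[0] / model.eigenvalues.sum() == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_predictors_r2_near_zero(self):
        rng = np.random.default_rng(2)
        n = 200
        X = _env(n, 2, seed=3)
        Y = rng.normal(size=(n, 10))
        assert fit_rda(Y, X).r2 < 0.05

    def test_fitted_values_match_lstsq_oracle(self):
        rng = np.random.default_rng(4)
        n, p, L = 25, 4, 12
        X = _env(n, p, seed=5)
        Y = rng.normal(size=(n, L))
        model = fit_rda(Y, X)
        Z = (X - X.mean()) / X.std(ddof=0)
        Yc = Y - Y.mean(axis=0)
        oracle = Z.to_numpy() @ np.linalg.pinv(Z.to_numpy()) @ Yc
        assert np.allclose(model.fitted, oracle, atol=1e-8)

    def test_collinear_predictors_named(self):
        X = _env(15, 2, seed=6)
        X["v3"] = X["v1"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_rda(np.random.default_rng(0).normal(size=(15, 5)), X)

    def test_too_few_populations(self):
        with pytest.raises(ValueError, match="populations"):
            fit_rda(np.zeros((3, 4)), _env(3, 5))


class TestForwardSelect:
    def test_perfect_predictor_selected_first(self):
        rng = np.random.default_rng(7)
        X = _env(30, 5, seed=8)
        Y = np.outer(X["v3"], rng.normal(size=8)) + rng.normal(0, 0.05, size=(30, 8))
        chosen = forward_select(Y, X, n_perm=199, seed=0)
        assert chosen[0] == "v3"

    def test_duplicated_variable_never_readmitted(self):
        rng = np.random.default_rng(9)
        X = _env(30, 3, seed=10)
        X["dup"] = X["v1"]
        Y = np.outer(X["v1"], rng.normal(size=6)) + rng.normal(0, 0.05, size=(30, 6))
        chosen = forward_select(Y, X, n_perm=199, seed=1)
        assert not {"v1", "dup"}.issubset(set(chosen))

    def test_pure_noise_selection_rate_near_alpha(self):
        # type-I calibration: expected selections ~ alpha * candidates
        rng = np.random.default_rng(11)
        picks = 0
        n_rep, n_cand = 50, 8
        for rep in range(n_rep):
            X = _env(20, n_cand, seed=100 + rep)
            Y = rng.normal(size=(20, 10))
            picks += len(forward_select(Y, X, n_perm=199, alpha=0.01, seed=rep))
        rate = picks / (n_rep * n_cand)
        assert rate < 0.04  # ~0.01 expected; generous upper bound


class TestGeoPcoa:
    def test_distances_reconstructed(self):
        rng = np.random.default_rng(12)
        lon = rng.uniform(0, 10, 12)
        lat = rng.uniform(45, 55, 12)
        coords = geo_pcoa(lon, lat, n_coords=10)
        D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        D2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(D, D2, rtol=0.05, atol=5.0)

    def test_collinear_arc_one_dominant_axis(self):
        lon = np.linspace(0, 3, 8)
        lat = np.full(8, 50.0)
        coords = geo_pcoa(lon, lat)
        var = coords.var(axis=0)
        assert var[0] / var.sum() > 0.99


class TestPartialRda:
    def test_climate_only_truth(self):
        rng = np.random.default_rng(13)
        n = 40
        clim = _env(n, 3, seed=14, names=["c1", "c2", "c3"])
        geo = _env(n, 2, seed=15, names=["g1", "g2"])
        plo = rng.choice([2.0, 4.0], size=(n, 1))
        Y = np.outer(clim["c1"], rng.normal(size=20))
        Y += rng.normal(0, 0.05, size=Y.shape)
        out = partial_rda_decomposition(Y, {"climate": clim, "geography": geo,
                                            "ploidy": plo})
        assert out["unique_climate"] > 0.5
        assert abs(out["unique_geography"]) < 0.05
        assert abs(out["unique_ploidy"]) < 0.05

    def test_duplicated_blocks_all_shared(self):
        rng = np.random.default_rng(16)
        n = 30
        A = _env(n, 2, seed=17)
        Y = np.outer(A["v1"], rng.normal(size=8)) + rng.normal(0, 0.1, size=(n, 8))
        out = partial_rda_decomposition(Y, {"a": A, "b": A.copy()})
        assert out["unique_a"] == pytest.approx(0.0, abs=1e-9)
        assert out["unique_b"] == pytest.approx(0.0, abs=1e-9)

    def test_fractions_sum_to_full(self):
        rng = np.random.default_rng(18)
        n = 35
        blocks = {
            "a": _env(n, 2, seed=19),
            "b": _env(n, 2, seed=20),
        }
        Y = rng.normal(size=(n, 12))
        out = partial_rda_decomposition(Y, blocks)
        total = out["unique_a"] + out["unique_b"] + out["shared"]
        assert total == pytest.approx(out["full"], abs=1e-9)


def _grid(n=50, seed=21, names=("v1", "v2", "v3")):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, len(names))), columns=list(names))
    df.insert(0, "pixel", [f"px{i}" for i in range(n)])
    df.insert(1, "lon", rng.uniform(0, 10, n))
    df.insert(2, "lat", rng.uniform(45, 55, n))
    return df


class TestAdaptiveIndex:
    def _model(self):
        X = _env(20, 3, seed=22)
        rng = np.random.default_rng(23)
        Y = np.outer(X["v1"] + 0.5 * X["v2"], rng.normal(size=10))
        Y += rng.normal(0, 0.1, size=Y.shape)
        return fit_rda(Y, X), X

    def test_training_mean_pixel_maps_to_origin(self):
        model, X = self._model()
        grid = _grid(5)
        grid.loc[0, ["v1", "v2", "v3"]] = X.mean().to_numpy()
        idx = adaptive_index(model, grid, scale=False)
        assert idx.pixels.loc[0, ["raw1", "raw2"]].abs().max() < 1e-9

    def test_identical_pixels_identical_indices(self):
        model, _ = self._model()
        grid = _grid(4)
        grid.loc[1, ["v1", "v2", "v3"]] = grid.loc[0, ["v1", "v2", "v3"]].to_numpy()
        idx = adaptive_index(model, grid)
        assert idx.pixels.loc[0, "index1"] == pytest.approx(idx.pixels.loc[1, "index1"])

    def test_linearity_before_scaling(self):
        model, X = self._model()
        grid = _grid(6)
        scaled = grid.copy()
        mu = X.mean()
        for v in ["v1", "v2", "v3"]:
            scaled[v] = mu[v] + 3.0 * (grid[v] - mu[v])
        a = adaptive_index(model, grid, scale=False).pixels
        b = adaptive_index(model, scaled, scale=False).pixels
        assert np.allclose(b["raw1"], 3.0 * a["raw1"], atol=1e-9)

    def test_missing_variable_rejected(self):
        model, _ = self._model()
        grid = _grid(4).drop(columns="v2")
        with pytest.raises(ValueError, match="v2"):
            adaptive_index(model, grid)


class TestClimaticDistance:
    def test_identical_models_zero_distance(self):
        X = _env(20, 3, seed=24)
        rng = np.random.default_rng(25)
        Y = np.outer(X["v1"], rng.normal(size=10)) + rng.normal(0, 0.1, (20, 10))
        m1 = fit_rda(Y, X)
        m2 = fit_rda(Y.copy(), X)
        grid = _grid(30)
        d = climatic_distance(adaptive_index(m1, grid), adaptive_index(m2, grid))
        assert d["distance"].abs().max() < 1e-9
        assert (d["normalized_distance"] == 0).all()

    def test_single_differing_pixel_is_one(self):
        X = _env(20, 3, seed=26)
        rng = np.random.default_rng(27)
        Y = np.outer(X["v1"], rng.normal(size=10)) + rng.normal(0, 0.1, (20, 10))
        m = fit_rda(Y, X)
        grid = _grid(10)
        ga = adaptive_index(m, grid)
        gb = adaptive_index(m, grid)
        gb.pixels.loc[4, "index1"] += 1.0
        d = climatic_distance(ga, gb)
        assert d.loc[4, "normalized_distance"] == pytest.approx(1.0)
        assert (d.drop(index=4)["normalized_distance"] == 0).all()

    def test_rotation_invariance(self):
        X = _env(20, 3, seed=28)
        rng = np.random.default_rng(29)
        Y = np.outer(X["v1"], rng.normal(size=10)) + rng.normal(0, 0.1, (20, 10))
        m = fit_rda(Y, X)
        grid = _grid(15)
        ga = adaptive_index(m, grid)
        gb = adaptive_index(m, grid)
        gb.pixels["index1"] += 0.5  # displace b
        base = climatic_distance(ga, gb)["distance"].to_numpy()
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        for g in (ga, gb):
            xy = g.pixels[["index1", "index2"]].to_numpy() @ R.T
            g.pixels[["index1", "index2"]] = xy
        rot = climatic_distance(ga, gb)["distance"].to_numpy()
        assert np.allclose(base, rot, atol=1e-9)

    def test_disjoint_pixel_sets_error(self):
        X = _env(20, 3, seed=30)
        rng = np.random.default_rng(31)
        Y = np.outer(X["v1"], rng.normal(size=10)) + rng.normal(0, 0.1, (20, 10))
        m = fit_rda(Y, X)
        ga = adaptive_index(m, _grid(5))
        gb_grid = _grid(5)
        gb_grid["pixel"] = [f"qx{i}" for i in range(5)]
        gb = adaptive_index(m, gb_grid)
        with pytest.raises(ValueError, match="pixel"):
            climatic_distance(ga, gb)


class TestFutureOffset:
    def _model_grid(self):
        X = _env(20, 3, seed=32)
        rng = np.random.default_rng(33)
        Y = np.outer(X["v1"], rng.normal(size=10)) + rng.normal(0, 0.1, (20, 10))
        return fit_rda(Y, X), _grid(12)

    def test_identical_climates_zero_offset(self):
        model, grid = self._model_grid()
        off = future_offset(model, grid, grid.copy())
        assert off["offset"].abs().max() < 1e-12

    def test_uniform_shift_constant_offset(self):
        model, grid = self._model_grid()
        fut = grid.copy()
        fut["v1"] = fut["v1"] + 0.8
        off = future_offset(model, grid, fut)
        assert off["offset"].std() < 1e-9

    def test_doubling_shift_doubles_offset(self):
        model, grid = self._model_grid()
        f1, f2 = grid.copy(), grid.copy()
        f1["v2"] += 0.5
        f2["v2"] += 1.0
        o1 = future_offset(model, grid, f1)["offset"]
        o2 = future_offset(model, grid, f2)["offset"]
        assert np.allclose(o2, 2 * o1, atol=1e-9)


class TestGridOccupancy:
    def test_empty_table(self):
        assert grid_occupancy(pd.DataFrame(columns=["lon", "lat"])).empty

    def test_two_points_one_cell(self):
        occ = grid_occupancy(pd.DataFrame({"lon": [5.0, 5.01], "lat": [50.0, 50.01]}))
        assert len(occ) == 1 and occ["n"][0] == 2

    def test_boundary_half_open(self):
        km_per_deg = 2 * np.pi * 6371.0088 / 360.0
        lat_edge = 100.0 / km_per_deg * 56  # exactly on a row boundary
        occ = grid_occupancy(pd.DataFrame({"lon": [5.0], "lat": [lat_edge]}))
        assert len(occ) == 1 and occ["row"][0] == 56

    def test_adjusted_r2_formula(self):
        assert ezekiel_adj_r2(0.5, 21, 4) == pytest.approx(1 - 0.5 * 20 / 16)
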