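"""Variogram fitting, indicator kriging, and fireshed delineation."""

import numpy as np
import pandas as pd
import pytest

from firenet.communities import generate_communities
from firenet.fireshed import (
    ExposurePointSet,
    Fireshed,
    Variogram,
    VariogramModel,
    build_exposure_points,
    delineate_fireshed,
    fireshed_summary,
    fit_variogram,
    ignition_density,
    krige_exposure_surface,
)
from firenet.records import FireRecord
from firenet.spread import simulate_fire
from firenet.transmission import structures_exposed

from conftest import make_uniform_grid


def gaussian_field_sample(rng, n, nugget, psill, range_m, extent=20_000.0):
    """Exact draw from a Gaussian process with exponential variogram."""
    x = rng.uniform(0, extent, n)
    y = rng.uniform(0, extent, n)
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    cov = psill * np.exp(-d / range_m) + nugget * np.eye(n)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    z = L @ rng.standard_normal(n)
    return x, y, z


def point_set(x, y, values, community_id=0):
    n = len(x)
    points = pd.DataFrame({"fire_id": np.arange(n), "x": x, "y": y})
    ind = pd.DataFrame({community_id: values}, index=np.arange(n))
    return ExposurePointSet(points, ind, ind.copy())


class TestExposurePoints:
    def test_indicator_count_matches_recount_oracle(self, landscape, weather):
        layer = generate_communities(landscape, 2, 800, seed=6)
        rng = np.random.default_rng(2)
        firelist, perims = [], []
        for i in range(80):
            cell = int(rng.integers(0, landscape.n_cells))
            x, y = layer.grid.cell_center(cell // landscape.n_cols,
                                          cell % landscape.n_cols)
            rec = FireRecord(i, float(x), float(y), 0, 200, "human", 70.0,
                             10.0, 0.0, 0.05, 0.07, 0.09,
                             float(rng.uniform(20, 150)), 30.0)
            firelist.append(rec)
            perims.append(simulate_fire(layer.grid, rec))
        pts = build_exposure_points(perims, firelist, layer)
        for com in layer.communities:
            cid = com.community_id
            expected = sum(
                1 for p in perims
                if structures_exposed(p, layer).get(cid, 0.0) > 0
            )
            assert pts.indicator[cid].sum() == expected
            assert set(np.unique(pts.indicator[cid])) <= {0.0, 1.0}

    def test_mismatched_ids_rejected(self, landscape):
        layer = generate_communities(landscape, 1, 100, seed=6)
        rec = FireRecord(0, 500.0, 500.0, 0, 200, "human", 70.0, 10.0, 0.0,
                         0.05, 0.07, 0.09, 30.0, 30.0)
        p = simulate_fire(layer.grid, rec)
        p.fire_id = 99
        with pytest.raises(ValueError):
            build_exposure_points([p], [rec], layer)


class TestVariogram:
    def test_exponential_parameters_recovered_within_25pct(self):
        # domain much larger than the range so the sill is identifiable
        # from a single realization
        rng = np.random.default_rng(0)
        x, y, z = gaussian_field_sample(rng, 2000, nugget=0.02, psill=0.2,
                                        range_m=3000.0, extent=40_000.0)
        vg = Variogram(x, y, z, n_lags=20, max_lag=12_000.0).fit("exponential")
        assert vg.psill == pytest.approx(0.2, rel=0.25)
        assert vg.range_m == pytest.approx(3000.0, rel=0.25)
        assert vg.nugget == pytest.approx(0.02, abs=0.02)

    def test_shuffled_values_near_pure_nugget(self):
        rng = np.random.default_rng(4)
        x, y, z = gaussian_field_sample(rng, 1200, nugget=0.02, psill=0.2,
                                        range_m=3000.0)
        z_shuf = rng.permutation(z)
        vg = Variogram(x, y, z_shuf, n_lags=20, max_lag=12_000.0).fit()
        # no spatial structure: the curve is flat - gamma near the first
        # lag already matches gamma at the largest lag
        g_near = float(vg.gamma(vg.empirical["lag"].iloc[0]))
        g_far = float(vg.gamma(12_000.0))
        assert g_near == pytest.approx(g_far, rel=0.15)

    def test_constant_indicator_pure_nugget_path(self):
        pts = point_set(np.arange(50.0), np.arange(50.0), np.ones(50))
        with pytest.warns(UserWarning):
            vg = fit_variogram(pts, 0)
        assert vg.degenerate
        assert vg.psill == 0.0

    def test_semivariance_model_properties(self):
        vg = VariogramModel("exponential", 0.1, 0.4, 2000.0)
        h = np.linspace(0, 10_000, 200)
        g = vg.gamma(h)
        assert g[0] == 0.0  # exact at zero lag
        assert (np.diff(g) >= 0).all()
        assert g[1] >= 0.1  # nugget jump just above zero
        sph = VariogramModel("spherical", 0.0, 1.0, 2000.0)
        assert sph.gamma(2000.0) == pytest.approx(1.0)
        assert sph.gamma(5000.0) == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        pts = point_set(np.arange(10.0), np.arange(10.0),
                        np.r_[np.ones(5), np.zeros(5)])
        with pytest.raises(ValueError):
            fit_variogram(pts, 0)


class TestKriging:
    def test_zero_nugget_exact_interpolation(self):
        rng = np.random.default_rng(5)
        g = make_uniform_grid(n=20, cell_size=100.0)
        # data at cell centers so grid prediction hits the data points
        cells = rng.choice(g.n_cells, 40, replace=False)
        rr, cc = np.divmod(cells, g.n_cols)
        x, y = g.cell_center(rr, cc)
        z = rng.integers(0, 2, 40).astype(float)
        pts = point_set(np.asarray(x, float), np.asarray(y, float), z)
        vg = VariogramModel("exponential", 0.0, 0.25, 600.0)
        surf = krige_exposure_surface(pts, 0, vg, g)
        np.testing.assert_allclose(surf[rr, cc], z, atol=1e-6)

    def test_all_ones_gives_unit_surface(self):
        g = make_uniform_grid(n=15, cell_size=100.0)
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1500, 30)
        y = rng.uniform(0, 1500, 30)
        pts = point_set(x, y, np.ones(30))
        vg = VariogramModel("exponential", 0.01, 0.2, 500.0)
        surf = krige_exposure_surface(pts, 0, vg, g)
        np.testing.assert_allclose(surf, 1.0, atol=1e-6)

    def test_surface_decays_away_from_positive_cluster(self):
        g = make_uniform_grid(n=40, cell_size=100.0)
        rng = np.random.default_rng(7)
        # cluster of 1s bottom-left, 0s everywhere else
        x1 = rng.uniform(200, 800, 25)
        y1 = rng.uniform(200, 800, 25)
        x0 = rng.uniform(0, 4000, 150)
        y0 = rng.uniform(0, 4000, 150)
        keep = ~((x0 < 1000) & (y0 < 1000))
        x = np.r_[x1, x0[keep]]
        y = np.r_[y1, y0[keep]]
        z = np.r_[np.ones(25), np.zeros(keep.sum())]
        pts = point_set(x, y, z)
        vg = VariogramModel("exponential", 0.005, 0.2, 1200.0)
        surf = krige_exposure_surface(pts, 0, vg, g, max_neighbors=12)
        # sample along the diagonal ray leaving the cluster
        ray = [surf[5, 5], surf[8, 8], surf[10, 10], surf[32, 32]]
        assert ray[0] > ray[1] > ray[2] >= ray[3]
        assert surf.min() >= 0.0 and surf.max() <= 1.0

    def test_degenerate_variogram_constant_surface(self):
        g = make_uniform_grid(n=10, cell_size=100.0)
        pts = point_set(np.arange(10.0) * 90, np.arange(10.0) * 90,
                        np.r_[np.ones(4), np.zeros(6)])
        vg = VariogramModel("exponential", 0.24, 0.0, 1.0, degenerate=True)
        surf = krige_exposure_surface(pts, 0, vg, g)
        assert np.allclose(surf, 0.4)


class TestFireshed:
    def _grid(self):
        g = make_uniform_grid(n=10, cell_size=100.0)
        g.tenure_id[:, 5:] = 1
        g.tenure_labels = {0: "A", 1: "B"}
        return g

    def test_surface_below_threshold_empty(self):
        g = self._grid()
        fs = delineate_fireshed(np.full((10, 10), 0.05), g, 0)
        assert fs.area_ha == 0.0
        assert fs.composition == {}

    def test_unit_surface_covers_grid_with_composition(self):
        g = self._grid()
        dens = np.full((10, 10), 1.0)
        fs = delineate_fireshed(np.ones((10, 10)), g, 0, density=dens)
        assert fs.area_ha == 100.0
        assert fs.composition == {"A": 50.0, "B": 50.0}

    def test_mask_monotone_in_both_thresholds(self):
        g = self._grid()
        rng = np.random.default_rng(8)
        surf = rng.random((10, 10))
        dens = rng.random((10, 10)) * 1e-3
        prev = None
        for thr in (0.05, 0.2, 0.5, 0.9):
            fs = delineate_fireshed(surf, g, 0, thr, dens, 1.5e-4)
            if prev is not None:
                assert (fs.mask <= prev).all()
            prev = fs.mask
        prev = None
        for min_d in (0.0, 1e-4, 5e-4, 1e-3):
            fs = delineate_fireshed(surf, g, 0, 0.1, dens, min_d)
            if prev is not None:
                assert (fs.mask <= prev).all()
            prev = fs.mask

    def test_identical_firesheds_full_overlap(self):
        g = self._grid()
        mask = np.zeros((10, 10), bool)
        mask[:3, :3] = True
        fs = [Fireshed(i, mask, 9.0, {"A": 9.0}) for i in range(2)]
        s = fireshed_summary(fs, g)
        assert s["overlap_fraction"] == 1.0
        assert s["union_area_ha"] == 9.0

    def test_disjoint_firesheds_no_overlap(self):
        g = self._grid()
        m1 = np.zeros((10, 10), bool)
        m1[:2, :2] = True
        m2 = np.zeros((10, 10), bool)
        m2[5:7, 5:7] = True
        s = fireshed_summary([Fireshed(0, m1, 4.0, {"A": 4.0}),
                              Fireshed(1, m2, 4.0, {"B": 4.0})], g)
        assert s["overlap_fraction"] == 0.0
        assert s["union_area_ha"] == 8.0
        assert s["union_composition_ha"] == {"A": 4.0, "B": 4.0}

    def test_transmission_efficiency_reference_diagonal(self):
        # 4 structures/yr over 2,000 fireshed ha -> 2 per 1,000 ha
        g = self._grid()
        mask = np.ones((10, 10), bool)
        fs = Fireshed(0, mask, 100.0, {"A": 50.0, "B": 50.0})
        fs.composition["A"] = 2000.0  # override for the arithmetic check
        fs.area_ha = 2050.0
        fs2 = Fireshed(0, mask, fs.area_ha, fs.composition)
        rate = pd.DataFrame({"community_id": [0], "tenure": ["A"],
                             "structures_per_yr": [4.0]})
        s = fireshed_summary([fs2], g, structures_rate=rate)
        eff = s["transmission_efficiency"]
        assert eff["structures_per_1000ha"].iloc[0] == pytest.approx(2.0)

    def test_ignition_density_integrates_to_count(self):
        g = make_uniform_grid(n=30, cell_size=100.0)
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.uniform(0, 3000, 500),
                           "y": rng.uniform(0, 3000, 500)})
        dens = ignition_density(df, g, bandwidth_m=200.0)
        total = dens.sum() * (g.cell_size / 1000.0) ** 2
        # mass is conserved up to smoothing loss past the grid edge
        assert 0.85 * 500 < total <= 500 + 1e-6
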