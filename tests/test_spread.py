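"""MTT fire growth: directional kernel, Dijkstra oracle, burn metrics."""

import math

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from firenet.records import FireRecord
from firenet.spread import (
    FLAME_BIN_WIDTH,
    N_FLAME_BINS,
    _ellipse_params,
    _intermediates,
    _OFFSETS_16_EXTRA,
    _OFFSETS_8,
    accumulate_burn_metrics,
    directional_rate,
    flame_bin_midpoints,
    moisture_factor,
    read_perimeters,
    simulate_fire,
    spread_arrival,
    write_perimeters,
)

from conftest import make_uniform_grid


def make_record(x, y, wind_speed=0.0, wind_dir=0.0, fm1=1e-9,
                burn_period=60.0, cause="natural", fire_id=0, year=0):
    return FireRecord(fire_id, x, y, year, 200, cause, 80.0, wind_speed,
                      wind_dir, fm1, 0.05, 0.07, burn_period, 50.0)


class TestDirectionalRate:
    def test_no_wind_isotropic(self):
        rates = [directional_rate(10.0, 0.0, t, 1.0) for t in (0, 45, 90, 180)]
        assert np.allclose(rates, 10.0)

    def test_head_exceeds_flank_exceeds_backing(self):
        head = directional_rate(1.0, 20.0, 0.0, 1.0)
        flank = directional_rate(1.0, 20.0, 90.0, 1.0)
        back = directional_rate(1.0, 20.0, 180.0, 1.0)
        assert head > flank > back > 0

    def test_head_to_backing_ratio_matches_ellipse_formula(self):
        # independent evaluation: LB = 1 + 0.25*10 = 3.5 at 10 m/s,
        # eps = sqrt(1 - 1/LB^2), head/backing = (1+eps)/(1-eps)
        wind_kmh = 36.0  # 10 m/s
        lb = 1.0 + 0.25 * 10.0
        eps = math.sqrt(1.0 - 1.0 / lb ** 2)
        expected = (1.0 + eps) / (1.0 - eps)
        ratio = (directional_rate(1.0, wind_kmh, 0.0, 1.0)
                 / directional_rate(1.0, wind_kmh, 180.0, 1.0))
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_head_rate_is_base_times_lb(self):
        assert directional_rate(2.0, 36.0, 0.0, 0.5) == pytest.approx(
            2.0 * 0.5 * 3.5
        )

    def test_lb_capped_at_8(self):
        lb, _ = _ellipse_params(3.6 * 100)
        assert lb == 8.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            directional_rate(-1.0, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            directional_rate(1.0, 0.0, 0.0, 0.0)


def brute_force_arrival(grid, ignition_cell, wind_speed, wind_dir, moist,
                        neighbors=16):
    """Independent all-pairs shortest path via scipy csgraph."""
    n_rows, n_cols = grid.n_rows, grid.n_cols
    base = grid.base_rate.ravel()
    offsets = list(_OFFSETS_8) + (
        list(_OFFSETS_16_EXTRA) if neighbors == 16 else []
    )
    wrad = np.radians(wind_dir)
    wvec = np.array([np.cos(wrad), np.sin(wrad)])
    rows_i, cols_j, weights = [], [], []
    for dr, dc in offsets:
        svec = np.array([dc, dr], float)
        cos_t = svec @ wvec / np.linalg.norm(svec)
        lb, eps = _ellipse_params(wind_speed)
        k = moist * lb * (1 - eps) / (1 - eps * cos_t)
        dist = np.hypot(dr, dc) * grid.cell_size
        for r in range(n_rows):
            for c in range(n_cols):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                a, b = r * n_cols + c, rr * n_cols + cc
                if base[a] <= 0 or base[b] <= 0:
                    continue
                if max(abs(dr), abs(dc)) > 1:
                    ok = any(
                        0 <= r + ir < n_rows and 0 <= c + ic < n_cols
                        and base[(r + ir) * n_cols + (c + ic)] > 0
                        for ir, ic in _intermediates(dr, dc)
                    )
                    if not ok:
                        continue
                rate = 0.5 * (base[a] + base[b]) * k
                rows_i.append(a)
                cols_j.append(b)
                weights.append(dist / rate)
    g = coo_matrix((weights, (rows_i, cols_j)),
                   shape=(grid.n_cells, grid.n_cells))
    return csgraph_dijkstra(g.tocsr(), indices=ignition_cell)


class TestSimulateFire:
    def test_tiny_burn_period_single_cell(self, uniform_grid):
        rec = make_record(1515, 1515, burn_period=1e-6)
        p = simulate_fire(uniform_grid, rec)
        assert p.cells.tolist() == [p.ignition_cell]
        assert p.arrival_min[0] == 0.0
        assert p.area_ha == pytest.approx(uniform_grid.cell_area_ha)

    @pytest.mark.parametrize("burn_period", [40.0, 60.0])
    def test_no_wind_circle_closed_form(self, uniform_grid, burn_period):
        # uniform rate r, no wind: burned area ~ pi*(r*T)^2 / 1e4 ha
        rec = make_record(1515, 1515, burn_period=burn_period)
        p = simulate_fire(uniform_grid, rec)
        analytic = math.pi * (15.0 * burn_period) ** 2 / 1e4
        assert abs(p.area_ha - analytic) / analytic < 0.08

    def test_zero_rate_row_blocks_spread(self):
        g = make_uniform_grid(n=31)
        g.base_rate[15, :] = 0.0
        rec = make_record(5 * 30 + 15, 5 * 30 + 15, burn_period=1e9)
        p = simulate_fire(g, rec)
        rows = p.cells // g.n_cols
        assert rows.max() < 15  # nothing beyond the fuel break

    def test_ignition_on_zero_rate_cell_flagged(self):
        g = make_uniform_grid(n=11)
        g.base_rate[5, 5] = 0.0
        rec = make_record(5 * 30 + 15, 5 * 30 + 15, burn_period=100.0)
        p = simulate_fire(g, rec)
        assert p.non_spreading
        assert p.cells.size == 1

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("neighbors", [8, 16])
    def test_arrival_equals_brute_force_oracle(self, seed, neighbors):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        g = make_uniform_grid(n=n, cell_size=50.0)
        g.base_rate = rng.uniform(0.0, 20.0, (n, n))
        g.base_rate[g.base_rate < 3.0] = 0.0  # some unburnable cells
        burnable = np.flatnonzero(g.base_rate.ravel() > 0)
        ign = int(rng.choice(burnable))
        wind = float(rng.uniform(0, 40))
        wdir = float(rng.uniform(0, 360))
        cells, arrival, _ = spread_arrival(g, ign, wind, wdir, 0.8, np.inf,
                                           neighbors)
        oracle = brute_force_arrival(g, ign, wind, wdir, 0.8, neighbors)
        finite = np.isfinite(oracle)
        assert set(cells.tolist()) == set(np.flatnonzero(finite).tolist())
        order = np.argsort(cells)
        np.testing.assert_allclose(
            arrival[order], oracle[cells[order]], rtol=1e-9, atol=1e-9
        )

    def test_burned_set_monotone_in_burn_period_and_rate(self, uniform_grid):
        rec_small = make_record(1515, 1515, wind_speed=20, burn_period=30.0)
        rec_large = make_record(1515, 1515, wind_speed=20, burn_period=60.0)
        a = set(simulate_fire(uniform_grid, rec_small).cells.tolist())
        b = set(simulate_fire(uniform_grid, rec_large).cells.tolist())
        assert a <= b
        fast = make_uniform_grid(rate=30.0)
        c = set(simulate_fire(fast, rec_small).cells.tolist())
        assert a <= c

    def test_wind_rotation_rotates_burned_set(self):
        g = make_uniform_grid(n=81)
        center = 40 * 81 + 40
        x = y = (40 + 0.5) * 30.0
        p0 = simulate_fire(g, make_record(x, y, wind_speed=36, wind_dir=0.0,
                                          burn_period=30.0))
        p90 = simulate_fire(g, make_record(x, y, wind_speed=36, wind_dir=90.0,
                                           burn_period=30.0))
        # rotate p0 by 90 deg about the ignition: (dx,dy)->(-dy,dx)
        r0, c0 = np.divmod(p0.cells, 81)
        rot = set(zip((40 + (c0 - 40)).tolist(), (40 - (r0 - 40)).tolist()))
        r9, c9 = np.divmod(p90.cells, 81)
        got = set(zip(r9.tolist(), c9.tolist()))
        jac = len(rot & got) / len(rot | got)
        assert jac >= 0.95

    def test_wind_elongates_downwind(self):
        g = make_uniform_grid(n=81)
        x = y = 40.5 * 30.0
        p = simulate_fire(g, make_record(x, y, wind_speed=54, wind_dir=0.0,
                                         burn_period=20.0))
        r, c = np.divmod(p.cells, 81)
        # wind toward +x: more spread in +col than -col
        assert (c.max() - 40) > 2 * (40 - c.min())

    def test_perimeter_roundtrip(self, tmp_path, uniform_grid):
        ps = [simulate_fire(uniform_grid, make_record(1515, 1515, fire_id=i,
                                                      burn_period=20.0))
              for i in range(3)]
        write_perimeters(ps, tmp_path / "c.csv", tmp_path / "s.csv",
                         uniform_grid.n_cols)
        back = read_perimeters(tmp_path / "c.csv", tmp_path / "s.csv",
                               uniform_grid.n_cols)
        for a, b in zip(ps, back):
            np.testing.assert_array_equal(a.cells, b.cells)
            np.testing.assert_allclose(a.flame_m, b.flame_m)


class TestBurnMetrics:
    def test_single_fire_single_season_bp(self, uniform_grid):
        p = simulate_fire(uniform_grid, make_record(1515, 1515,
                                                    burn_period=20.0))
        m = accumulate_burn_metrics([p], 1, 1, uniform_grid)
        assert np.allclose(m.bp[p.cells], 1.0)
        assert m.bp.sum() == p.cells.size
        assert np.allclose(m.bp, m.bp_per_fire)

    def test_constant_flame_single_bin(self, uniform_grid):
        p = simulate_fire(uniform_grid, make_record(1515, 1515,
                                                    burn_period=20.0))
        p.flame_m = np.full(p.cells.size, 1.2)
        m = accumulate_burn_metrics([p], 1, 1, uniform_grid)
        cell = p.cells[0]
        assert m.flame_bin_probs[cell, 2] == 1.0  # bin 3 covers [1.0, 1.5)
        assert m.cfl[cell] == pytest.approx(1.25)

    def test_uniform_bins_give_cfl_5m(self):
        probs = np.full(N_FLAME_BINS, 1.0 / N_FLAME_BINS)
        assert probs @ flame_bin_midpoints() == pytest.approx(5.0)

    def test_bin_probabilities_sum_to_one_where_burned(self, uniform_grid):
        ps = [simulate_fire(uniform_grid,
                            make_record(1515 + 90 * i, 1515, fire_id=i,
                                        year=i % 2, burn_period=25.0))
              for i in range(4)]
        m = accumulate_burn_metrics(ps, 4, 2, uniform_grid)
        burned = m.burn_count > 0
        np.testing.assert_allclose(m.flame_bin_probs[burned].sum(axis=1), 1.0,
                                   atol=1e-9)
        assert (m.bp >= 0).all() and (m.bp <= 1).all()
        assert m.cfl[burned].min() >= 0.25 and m.cfl[burned].max() <= 9.75

    def test_empty_perimeter_list_all_zero(self, uniform_grid):
        m = accumulate_burn_metrics([], 0, 1, uniform_grid)
        assert m.bp.sum() == 0 and m.cfl.sum() == 0

    def test_moisture_factor_range(self):
        assert moisture_factor(0.0) == 1.0
        assert moisture_factor(0.5) == pytest.approx(0.05)
        assert 0 < moisture_factor(0.2) < 1
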