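"""Bias correction, upper temperatures, sea graph and analogue search."""

import networkx as nx
import numpy as np
import pytest

from oceanexposure.analogues import (
    build_sea_graph,
    delta_bias_correct,
    future_upper_temperature,
    haversine_km,
    hovmoller,
    htm_upper_temperature,
    nearest_analogue,
    realm_crossing_summary,
    redistribution_rate,
)
from oceanexposure.grids import GriddedField, GridSpec, SSTSeries


def series(grid, years, values, era="past"):
    sst = np.broadcast_to(values, (len(years), *grid.shape)).copy()
    sst[:, grid.land_mask] = np.nan
    return SSTSeries(grid, np.asarray(years), sst, era)


class TestDeltaBiasCorrect:
    def _pair(self, rng, shift=0.0):
        g = GridSpec.regular(45.0)
        years = np.arange(1840, 1960)
        past = series(g, years, 10.0)
        past.sst += rng.normal(0, 0.1, past.sst.shape)
        ref = SSTSeries(g, years, past.sst + shift, "historical")
        return past, ref

    def test_identical_overlap_means_leave_series_unchanged(self, rng):
        past, ref = self._pair(rng)
        out = delta_bias_correct(past, ref, (1851, 1950))
        np.testing.assert_allclose(out.sst, past.sst)

    def test_constant_reference_offset_shifts_constantly(self, rng):
        past, ref = self._pair(rng, shift=1.0)
        out = delta_bias_correct(past, ref, (1851, 1950))
        np.testing.assert_allclose(out.sst, past.sst + 1.0, rtol=1e-12)

    def test_per_cell_delta_matches_two_mean_oracle(self, rng):
        g = GridSpec.regular(45.0)
        years = np.arange(1851, 1951)
        past = series(g, years, 10.0)
        past.sst += rng.normal(0, 1, past.sst.shape)
        ref = series(g, years, 12.0, "historical")
        ref.sst += rng.normal(0, 1, ref.sst.shape)
        out = delta_bias_correct(past, ref, (1851, 1950))
        delta = out.sst[0] - past.sst[0]
        expected = ref.sst.mean(axis=0) - past.sst.mean(axis=0)
        np.testing.assert_allclose(delta, expected, rtol=1e-10)

    def test_missing_overlap_errors(self, rng):
        past, ref = self._pair(rng)
        with pytest.raises(ValueError, match="not covered"):
            delta_bias_correct(past, ref, (1700, 1800))


class TestUpperTemperatures:
    def test_constant_series(self):
        g = GridSpec.regular(45.0)
        s = series(g, np.arange(1000, 1300), 17.5)
        out = htm_upper_temperature(s, window_ce=(1100, 1200))
        assert np.allclose(out.values, 17.5)

    def test_spike_inside_vs_outside_window(self):
        g = GridSpec.regular(45.0)
        s = series(g, np.arange(2000, 2101), 10.0)
        s.sst[50] += 5.0  # year 2050, inside
        s.sst[95] += 9.0  # year 2095, outside [2020, 2060]
        out = future_upper_temperature(s, (2020, 2060))
        assert np.allclose(out.values, 15.0)

    def test_sinusoid_matches_scan_oracle(self, rng):
        g = GridSpec.regular(45.0)
        years = np.arange(0, 500)
        s = series(g, years, 0.0)
        wave = np.sin(2 * np.pi * years / 170.0)[:, None, None]
        s.sst = s.sst + wave + rng.normal(0, 0.1, s.sst.shape)
        out = htm_upper_temperature(s, window_ce=(120, 310))
        sel = (years >= 120) & (years <= 310)
        expected = s.sst[sel].max(axis=0)  # brute-force scan
        np.testing.assert_allclose(out.values, expected)

    def test_monotone_warming_takes_final_year(self):
        g = GridSpec.regular(45.0)
        years = np.arange(1851, 2101)
        s = series(g, years, 0.0, era="future_scenario_a")
        s.sst = s.sst + 0.01 * (years - 1851)[:, None, None]
        out = future_upper_temperature(s, (2080, 2100))
        assert np.allclose(out.values, 0.01 * (2100 - 1851))


# ---------------------------------------------------------------------------
# sea graph


def patch_grid(res, ocean_block):
    """Global grid that is all land except an ocean patch (no dateline wrap)."""
    g = GridSpec.regular(res)
    land = np.ones(g.shape, bool)
    land[ocean_block] = False
    return g.with_land(land)


class TestBuildSeaGraph:
    def test_three_by_three_patch_has_twenty_edges(self):
        g = patch_grid(60.0, (slice(0, 3), slice(1, 4)))
        graph = build_sea_graph(g, connectivity=8)
        assert graph.matrix.nnz == 40  # 20 undirected edges (12 orth + 8 diag)
        assert build_sea_graph(g, connectivity=4).matrix.nnz == 24

    def test_equatorial_edge_weight_is_haversine(self):
        g = GridSpec.regular(36.0)  # rows at -72, -36, 0, 36, 72
        graph = build_sea_graph(g)
        i = 2  # equator row
        a, b = graph.node_of_cell[i, 0], graph.node_of_cell[i, 1]
        expected = haversine_km(0.0, g.lon_centers[0], 0.0, g.lon_centers[1])
        assert graph.matrix[a, b] == pytest.approx(expected, rel=1e-12)
        assert haversine_km(0.0, 0.0, 0.0, 2.5) == pytest.approx(278.0, abs=0.1)

    def test_straight_equatorial_run_equals_haversine(self):
        from scipy.sparse.csgraph import dijkstra

        g = GridSpec.regular(36.0)
        graph = build_sea_graph(g)
        d = dijkstra(graph.matrix, directed=False, indices=graph.node_of_cell[2, 0])
        for steps in (1, 2, 3):
            target = graph.node_of_cell[2, steps]
            direct = haversine_km(0.0, g.lon_centers[0], 0.0, g.lon_centers[steps])
            assert d[target] == pytest.approx(direct, abs=1e-6)

    def test_dateline_wrap_shortens_paths(self):
        from scipy.sparse.csgraph import dijkstra

        g = GridSpec.regular(36.0)
        graph = build_sea_graph(g)
        d = dijkstra(graph.matrix, directed=False, indices=graph.node_of_cell[2, 0])
        # one wrap step west instead of nine steps east
        assert d[graph.node_of_cell[2, g.nlon - 1]] == pytest.approx(
            haversine_km(0, 0, 0, 36.0), rel=1e-9
        )

    def test_no_corner_cutting_through_diagonal_land(self):
        # ocean on a 2x2 checkerboard: diagonal neighbours with both shared
        # orthogonal cells land must not connect
        g = patch_grid(45.0, (slice(0, 2), slice(1, 3)))
        land = g.land_mask.copy()
        land[0, 2] = True
        land[1, 1] = True
        g2 = g.with_land(land)  # ocean at (0,1) and (1,2) only, diagonal
        graph = build_sea_graph(g2, connectivity=8)
        assert graph.matrix.nnz == 0

    def test_opening_a_strait_never_increases_distances(self, rng):
        from scipy.sparse.csgraph import dijkstra

        g = GridSpec.regular(18.0)
        land = rng.random(g.shape) < 0.35
        g1 = g.with_land(land)
        land2 = land.copy()
        opened = rng.random(g.shape) < 0.1
        land2[opened] = False
        g2 = g.with_land(land2)
        gr1, gr2 = build_sea_graph(g1), build_sea_graph(g2)
        common = np.argwhere(g1.ocean_mask)
        src = tuple(common[0])
        d1 = dijkstra(gr1.matrix, directed=False, indices=gr1.node_of_cell[src])
        d2 = dijkstra(gr2.matrix, directed=False, indices=gr2.node_of_cell[src])
        for i, j in common[1:]:
            a, b = d1[gr1.node_of_cell[i, j]], d2[gr2.node_of_cell[i, j]]
            if np.isfinite(a):
                assert b <= a + 1e-9


# ---------------------------------------------------------------------------
# nearest analogue vs a brute-force oracle


def oracle_graph(grid, connectivity=8):
    """Independent edge enumeration: explicit loops and modular longitude."""
    G = nx.Graph()
    nlat, nlon = grid.shape
    ocean = grid.ocean_mask
    for i in range(nlat):
        for j in range(nlon):
            if not ocean[i, j]:
                continue
            G.add_node((i, j))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0 or (connectivity == 4 and di and dj):
                        continue
                    ii, jj = i + di, (j + dj) % nlon
                    if not (0 <= ii < nlat) or not ocean[ii, jj]:
                        continue
                    if di and dj and not (ocean[i, jj] or ocean[ii, j]):
                        continue  # corner cutting blocked
                    w = haversine_km(
                        grid.lat_centers[i], grid.lon_centers[j], grid.lat_centers[ii], grid.lon_centers[jj]
                    )
                    G.add_edge((i, j), (ii, jj), weight=float(w))
    return G


def oracle_nearest(grid, focal, htm, fut, candidate, tol=0.0, connectivity=8):
    """Brute-force: full Dijkstra tree + exhaustive filter and tie-break."""
    G = oracle_graph(grid, connectivity)
    dist = nx.single_source_dijkstra_path_length(G, focal, weight="weight")
    best = None
    for (i, j), d in dist.items():
        if not candidate[i, j] or not np.isfinite(fut[i, j]):
            continue
        if fut[i, j] > htm[focal] + tol:
            continue
        key = (d, fut[i, j], i * grid.nlon + j)
        if best is None or key < best:
            best = key
    if best is None:
        return None, np.nan
    d, _, flat = best
    return (flat // grid.nlon, flat % grid.nlon), d


class TestNearestAnalogue:
    def test_self_analogue_distance_zero(self):
        g = GridSpec.regular(36.0)
        graph = build_sea_graph(g)
        htm = GriddedField(g, np.full(g.shape, 20.0))
        fut = GriddedField(g, np.full(g.shape, 19.0))
        (r,) = nearest_analogue([(2, 4)], htm, fut, graph)
        assert r.target_cell == (2, 4)
        assert r.sea_distance_km == 0.0

    def test_closed_barrier_yields_no_analogue(self):
        from oceanexposure.synthetic import WorldConfig, generate_masks

        _, grid, _ = generate_masks(WorldConfig.demo(0, barrier_closed=True))
        graph = build_sea_graph(grid)
        bcol = grid.nlon // 2
        htm = GriddedField(grid, np.where(grid.ocean_mask, 10.0, np.nan))
        fut_vals = np.where(grid.ocean_mask, 99.0, np.nan)
        fut_vals[:, bcol + 1 : bcol + 3] = 5.0  # only analogues: other basin
        fut_vals[grid.land_mask] = np.nan
        fut = GriddedField(grid, fut_vals)
        (r,) = nearest_analogue([(9, 2)], htm, fut, graph)
        assert not r.has_analogue
        assert np.isnan(r.sea_distance_km)

    def test_focal_on_land_rejected(self, demo_world):
        graph = build_sea_graph(demo_world.grid)
        f = GriddedField(demo_world.grid, np.zeros(demo_world.grid.shape))
        land_cell = tuple(np.argwhere(demo_world.grid.land_mask)[0])
        with pytest.raises(ValueError, match="land"):
            nearest_analogue([land_cell], f, f, graph)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_layouts(self, seed):
        r = np.random.default_rng(seed)
        g = GridSpec.regular(12.0)  # 15 latitude rows
        land = r.random(g.shape) < 0.4
        grid = g.with_land(land)
        if not grid.ocean_mask.any():
            return
        graph = build_sea_graph(grid)
        htm_v = np.where(grid.ocean_mask, r.uniform(10, 20, g.shape), np.nan)
        fut_v = np.where(grid.ocean_mask, r.uniform(10, 25, g.shape), np.nan)
        htm = GriddedField(grid, htm_v)
        fut = GriddedField(grid, fut_v)
        ocean_cells = np.argwhere(grid.ocean_mask)
        focal = [tuple(c) for c in ocean_cells[r.choice(len(ocean_cells), size=min(5, len(ocean_cells)), replace=False)]]
        results = nearest_analogue(focal, htm, fut, graph)
        for res in results:
            t_exp, d_exp = oracle_nearest(grid, res.focal_cell, htm_v, fut_v, grid.ocean_mask)
            assert res.target_cell == t_exp
            if t_exp is not None:
                assert res.sea_distance_km == pytest.approx(d_exp, rel=1e-12)
                direct = haversine_km(
                    grid.lat_centers[res.focal_cell[0]],
                    grid.lon_centers[res.focal_cell[1]],
                    grid.lat_centers[t_exp[0]],
                    grid.lon_centers[t_exp[1]],
                )
                assert res.sea_distance_km >= direct - 1e-9

    def test_warming_future_never_shortens_distances(self, rng):
        g = GridSpec.regular(12.0)
        grid = g.with_land(rng.random(g.shape) < 0.3)
        graph = build_sea_graph(grid)
        htm_v = np.where(grid.ocean_mask, rng.uniform(10, 20, g.shape), np.nan)
        fut_v = np.where(grid.ocean_mask, rng.uniform(10, 25, g.shape), np.nan)
        focal = [tuple(c) for c in np.argwhere(grid.ocean_mask)[:10]]
        base = nearest_analogue(focal, GriddedField(grid, htm_v), GriddedField(grid, fut_v), graph)
        warm = nearest_analogue(focal, GriddedField(grid, htm_v), GriddedField(grid, fut_v + 0.5), graph)
        for b, w in zip(base, warm):
            if w.has_analogue:
                assert b.has_analogue
                assert w.sea_distance_km >= b.sea_distance_km - 1e-9

    def test_eez_restriction_never_shortens_distances(self, demo_world):
        graph = build_sea_graph(demo_world.grid)
        v = np.where(demo_world.grid.ocean_mask, 15.0, np.nan)
        htm = GriddedField(demo_world.grid, v)
        fut = GriddedField(demo_world.grid, v - 1.0)
        focal = [tuple(c) for c in np.argwhere(demo_world.grid.ocean_mask)[::7]]
        full = nearest_analogue(focal, htm, fut, graph)
        eez = nearest_analogue(focal, htm, fut, graph, demo_world.eez_mask)
        for a, b in zip(full, eez):
            if b.has_analogue:
                assert b.sea_distance_km >= a.sea_distance_km - 1e-9


class TestSummaries:
    def _results(self, grid):
        htm = GriddedField(grid, np.where(grid.ocean_mask, 20.0, np.nan))
        fut = GriddedField(grid, np.where(grid.ocean_mask, 19.0, np.nan))
        graph = build_sea_graph(grid)
        focal = [tuple(c) for c in np.argwhere(grid.ocean_mask)[:6]]
        return nearest_analogue(focal, htm, fut, graph)

    def test_all_self_analogues_zero_crossing(self, demo_world):
        results = self._results(demo_world.grid)
        s = realm_crossing_summary(results, demo_world.realm_ids.values)
        assert s["pct_crossing_realm"] == 0.0
        assert s["pct_no_analogue"] == 0.0

    def test_constructed_crossings_hand_count(self, demo_world):
        grid = demo_world.grid
        # single qualifying cell: every focal shares the same target
        htm = GriddedField(grid, np.where(grid.ocean_mask, 20.0, np.nan))
        fut_v = np.where(grid.ocean_mask, 25.0, np.nan)
        target = tuple(np.argwhere(grid.ocean_mask)[10])
        fut_v[target] = 10.0
        graph = build_sea_graph(grid)
        focal = [tuple(c) for c in np.argwhere(grid.ocean_mask)[:6] if tuple(c) != target]
        results = nearest_analogue(focal, htm, GriddedField(grid, fut_v), graph)
        assert all(r.target_cell == target for r in results)
        ids = np.where(grid.ocean_mask, 1.0, np.nan)
        ids[target] = 2  # focals in realm 1, shared target in realm 2
        for r in results[:2]:
            ids[r.focal_cell] = 2  # two focals share the target's realm
        s = realm_crossing_summary(results, ids)
        expected = 100 * (len(results) - 2) / len(results)
        assert s["pct_crossing_realm"] == pytest.approx(expected)

    def test_redistribution_rates(self, demo_world):
        results = self._results(demo_world.grid)
        rates = redistribution_rate(results, 70)
        assert np.allclose(rates, 0.0)  # self-analogues: zero distance
        results[0].sea_distance_km = 1625.0
        rates = redistribution_rate(results, 70)
        assert rates[0] == pytest.approx(1625 / 70)


class TestHovmoller:
    def test_constant_single_band(self):
        g = GridSpec.regular(45.0)
        s = series(g, np.arange(2000, 2010), 12.0)
        h = hovmoller(s, np.ones(g.shape, bool), band_width_deg=180.0)
        assert h.values.shape == (1, 10)
        assert np.allclose(h.values, 12.0)

    def test_two_cell_weighted_mean_oracle(self):
        g = GridSpec.regular(45.0)
        s = series(g, np.arange(0, 5), 0.0)
        hot = np.zeros(g.shape, bool)
        hot[2, 0] = hot[3, 0] = True  # lats 22.5 and 67.5
        s.sst[:, 2, 0] = 10.0
        s.sst[:, 3, 0] = 20.0
        h = hovmoller(s, hot, band_width_deg=90.0)  # one band spans 0..90
        w1, w2 = g.cell_area[2, 0], g.cell_area[3, 0]
        expected = (10 * w1 + 20 * w2) / (w1 + w2)
        np.testing.assert_allclose(h.values[1], expected)

    def test_empty_band_is_missing(self):
        g = GridSpec.regular(45.0)
        s = series(g, np.arange(0, 3), 5.0)
        hot = np.zeros(g.shape, bool)
        hot[0, 0] = True
        h = hovmoller(s, hot, band_width_deg=90.0)
        assert np.isnan(h.values[1]).all()
        assert np.isfinite(h.values[0]).all()

    def test_band_means_within_member_range(self, demo_world):
        s = demo_world.series["past"]
        hot = demo_world.grid.ocean_mask
        h = hovmoller(s, hot, band_width_deg=30.0)
        for b in range(h.values.shape[0]):
            sel = (s.grid.lat_centers >= h.band_edges[b]) & (s.grid.lat_centers < h.band_edges[b + 1])
            cells = hot & sel[:, None]
            if not cells.any():
                continue
            lo = np.nanmin(s.sst[:, cells], axis=1)
            hi = np.nanmax(s.sst[:, cells], axis=1)
            assert (h.values[b] >= lo - 1e-9).all() and (h.values[b] <= hi + 1e-9).all()
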