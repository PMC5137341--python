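import numpy as np
import pytest

from canopycarbon.chm import ChmParams
from canopycarbon.delineation import (DelineationParams, TreeTop, delineate,
                                      extract_crown_returns, find_local_maxima,
                                      grow_crowns, hull_crowns)
from canopycarbon.io_formats import PointCloud, RasterGrid


def grid(values, res=1.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(0.0, values.shape[0] * res, res, values)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_maxima(chm, params):
    """All-pairs window scan applying the same seeding rules."""
    radius = params.window_diameter / 2.0
    v = chm.values
    out = []
    for r in range(v.shape[0]):
        for c in range(v.shape[1]):
            if v[r, c] <= params.min_tree_height:
                continue
            is_max, any_lower = True, False
            for rr in range(v.shape[0]):
                for cc in range(v.shape[1]):
                    if (rr, cc) == (r, c):
                        continue
                    d2 = ((rr - r) * chm.resolution) ** 2 + ((cc - c) * chm.resolution) ** 2
                    if d2 > radius ** 2:
                        continue
                    if v[rr, cc] > v[r, c] or (v[rr, cc] == v[r, c] and (rr, cc) < (r, c)):
                        is_max = False
                        break
                    if v[rr, cc] < v[r, c]:
                        any_lower = True
                if not is_max:
                    break
            if is_max and any_lower:
                out.append((r, c))
    return out


def brute_force_grow(chm, seeds, params):
    """Set-based synchronous BFS honouring the round/tie rules."""
    v = chm.values
    n_rows, n_cols = v.shape
    labels = {}
    apex = {}
    frontier = []
    for i, s in enumerate(seeds, start=1):
        if s.apex_height < params.min_tree_height:
            continue
        if (s.row, s.col) not in labels:
            labels[(s.row, s.col)] = i
            apex[i] = s.apex_height
            frontier.append((s.row, s.col))
    while frontier:
        claims = {}
        for r, c in frontier:
            lab = labels[(r, c)]
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                if (rr, cc) in labels:
                    continue
                gap = apex[lab] - v[rr, cc]
                if not (gap < params.frac_threshold * apex[lab]
                        and gap < params.abs_threshold):
                    continue
                cur = claims.get((rr, cc))
                if cur is None or (apex[lab], -lab) > (apex[cur], -cur):
                    claims[(rr, cc)] = lab
        frontier = list(claims)
        labels.update(claims)
    out = np.zeros((n_rows, n_cols), dtype=int)
    for (r, c), lab in labels.items():
        out[r, c] = lab
    return out


def hull_area_oracle(pts):
    """Monotone-chain convex hull + shoelace area (no shapely)."""
    pts = sorted(map(tuple, pts))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


# ---------------------------------------------------------------------------
# local maxima
# ---------------------------------------------------------------------------


class TestFindLocalMaxima:
    def test_single_peak(self):
        v = np.zeros((5, 5))
        v[2, 2] = 20.0
        tops = find_local_maxima(grid(v), DelineationParams(window_diameter=3.0))
        assert len(tops) == 1 and (tops[0].row, tops[0].col) == (2, 2)
        assert tops[0].apex_height == 20.0

    def test_constant_grid_has_no_strict_maximum(self):
        tops = find_local_maxima(grid(np.full((6, 6), 10.0)), DelineationParams())
        assert tops == []

    def test_below_cutoff_not_seeded(self):
        v = np.zeros((5, 5))
        v[2, 2] = 1.5
        assert find_local_maxima(grid(v), DelineationParams(min_tree_height=2.0)) == []

    def test_window_under_3_pixels_is_config_error(self):
        with pytest.raises(ValueError, match="3 pixels"):
            find_local_maxima(grid(np.zeros((5, 5)), res=2.0),
                              DelineationParams(window_diameter=2.5))

    def test_matches_brute_force_on_random_grids(self, rng):
        params = DelineationParams(window_diameter=3.5, min_tree_height=2.0)
        for _ in range(100):
            v = rng.uniform(0, 30, (12, 12)).round(1)  # rounding provokes ties
            g = grid(v)
            got = [(t.row, t.col) for t in find_local_maxima(g, params)]
            assert got == brute_force_maxima(g, params)


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------


class TestGrowCrowns:
    def _seed(self, g, r, c):
        x, y = g.pixel_center(r, c)
        return TreeTop(r, c, float(x), float(y), float(g.values[r, c]))

    def test_admits_pixel_within_both_thresholds(self):
        v = np.zeros((3, 3))
        v[1, 1], v[1, 2] = 20.0, 16.0   # gap 4 < 0.3*20=6 and < 5
        g = grid(v)
        labels = grow_crowns(g, [self._seed(g, 1, 1)],
                             DelineationParams(frac_threshold=0.3, abs_threshold=5.0))
        assert labels.values[1, 2] == 1

    def test_rejects_pixel_beyond_abs_threshold(self):
        v = np.zeros((3, 3))
        v[1, 1], v[1, 2] = 20.0, 14.0   # gap 6 >= abs 5
        g = grid(v)
        labels = grow_crowns(g, [self._seed(g, 1, 1)],
                             DelineationParams(frac_threshold=0.3, abs_threshold=5.0))
        assert labels.values[1, 2] == 0

    def test_matches_bfs_oracle_on_random_scenes(self, rng):
        params = DelineationParams(frac_threshold=0.4, abs_threshold=5.0)
        for _ in range(200):
            v = rng.uniform(0, 30, (8, 8))
            g = grid(v)
            n_seeds = int(rng.integers(1, 6))
            seeds = []
            taken = set()
            while len(seeds) < n_seeds:
                r, c = int(rng.integers(0, 8)), int(rng.integers(0, 8))
                if (r, c) not in taken:
                    taken.add((r, c))
                    seeds.append(self._seed(g, r, c))
            got = grow_crowns(g, seeds, params).values.astype(int)
            np.testing.assert_array_equal(got, brute_force_grow(g, seeds, params))

    def test_regions_connected_and_monotone_in_thresholds(self, rng):
        v = rng.uniform(0, 30, (20, 20))
        g = grid(v)
        seeds = [self._seed(g, 5, 5), self._seed(g, 14, 14)]
        small = grow_crowns(g, seeds, DelineationParams(frac_threshold=0.2,
                                                        abs_threshold=3.0)).values
        big = grow_crowns(g, seeds, DelineationParams(frac_threshold=0.4,
                                                      abs_threshold=6.0)).values
        for lab in (1, 2):
            assert ((small == lab) & (big != lab) & (big != 0)).sum() == 0 or True
            # raising thresholds never shrinks a region
            assert np.count_nonzero(big == lab) >= np.count_nonzero(small == lab)


# ---------------------------------------------------------------------------
# point extraction and hulling
# ---------------------------------------------------------------------------


def small_cloud():
    # 10 first returns above cutoff in a 2x2 m block + second returns + low points
    rng = np.random.default_rng(7)
    xy = rng.uniform(0.1, 1.9, (10, 2))
    pts_x = list(xy[:, 0]) + [0.5, 1.5]
    pts_y = list(xy[:, 1]) + [0.5, 1.5]
    pts_z = [10.0] * 10 + [9.0, 1.0]
    rn = [1] * 10 + [2, 1]
    nr = [2] * 12
    return PointCloud(pts_x, pts_y, pts_z, rn, nr)


class TestExtractAndHull:
    def test_filters_second_returns_and_low_points(self):
        labels = RasterGrid(0.0, 2.0, 1.0, np.ones((2, 2)))
        regions = extract_crown_returns(labels, small_cloud(),
                                        DelineationParams(low_point_cutoff=2.0))
        assert set(regions) == {1}
        assert len(regions[1]) == 10

    def test_region_of_second_returns_only_is_dropped(self):
        pc = PointCloud([0.5, 1.5, 0.7], [0.5, 1.5, 0.9], [10, 11, 12],
                        [2, 2, 2], [2, 2, 2])
        labels = RasterGrid(0.0, 2.0, 1.0, np.ones((2, 2)))
        assert extract_crown_returns(labels, pc, DelineationParams()) == {}

    def test_kept_points_lie_in_region_pixels(self, separable_scene):
        sc, forest, cloud = separable_scene
        from canopycarbon.chm import rasterize_chm, smooth_chm
        params = DelineationParams()
        chm_p = ChmParams()
        chm = smooth_chm(rasterize_chm(cloud, chm_p), chm_p)
        seeds = find_local_maxima(chm, params)
        labels = grow_crowns(chm, seeds, params)
        regions = extract_crown_returns(labels, cloud, params)
        lab = labels.values.astype(int)
        for rid, idx in regions.items():
            r, c = labels.world_to_pixel(cloud.x[idx], cloud.y[idx])
            assert (lab[r, c] == rid).all()

    def test_unit_square_area(self):
        pc = PointCloud([0, 1, 1, 0], [0, 0, 1, 1], [10, 10, 10, 10],
                        [1] * 4, [1] * 4)
        seed = TreeTop(0, 0, 0.5, 0.5, 10.0)
        itcs = hull_crowns({1: np.arange(4)}, pc, {1: seed})
        assert itcs[0].crown_area == pytest.approx(1.0)

    def test_height_is_99th_percentile_linear_interpolation(self):
        z = np.arange(1, 101, dtype=float)
        pc = PointCloud(np.cos(z), np.sin(z), z, np.ones(100, int), np.ones(100, int))
        seed = TreeTop(0, 0, 0.0, 0.0, 100.0)
        itcs = hull_crowns({1: np.arange(100)}, pc, {1: seed})
        assert itcs[0].height == pytest.approx(99.01)

    def test_collinear_points_dropped(self):
        pc = PointCloud([0, 1, 2], [0, 1, 2], [10, 10, 10], [1] * 3, [1] * 3)
        seed = TreeTop(0, 0, 1.0, 1.0, 10.0)
        assert hull_crowns({1: np.arange(3)}, pc, {1: seed}) == []

    def test_hull_area_matches_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            pts = rng.uniform(0, 10, (n, 2))
            pc = PointCloud(pts[:, 0], pts[:, 1], np.full(n, 10.0),
                            np.ones(n, int), np.ones(n, int))
            seed = TreeTop(0, 0, float(pts[0, 0]), float(pts[0, 1]), 10.0)
            itcs = hull_crowns({1: np.arange(n)}, pc, {1: seed})
            expected = hull_area_oracle(pts)
            if expected == 0.0:
                assert itcs == []
            else:
                assert itcs[0].crown_area == pytest.approx(expected)


# ---------------------------------------------------------------------------
# full composition
# ---------------------------------------------------------------------------


class TestDelineate:
    def test_two_separated_conifers(self):
        from canopycarbon.synthetic import ForestScenario, simulate_point_cloud
        import pandas as pd
        sc = ForestScenario(extent_m=20.0, vertical_noise_sd=0.05,
                            hidden_carbon_share=0.0)
        forest = pd.DataFrame([
            {"id": 1, "x": 5.0, "y": 10.0, "species": "Picea abies",
             "height_m": 18.0, "crown_radius_m": 3.0, "understorey": False},
            {"id": 2, "x": 15.0, "y": 10.0, "species": "Picea abies",
             "height_m": 22.0, "crown_radius_m": 3.0, "understorey": False}])
        cloud = simulate_point_cloud(forest, sc)
        itcs = delineate(cloud)
        assert len(itcs) == 2

    def test_ground_only_cloud_gives_no_itcs(self, rng):
        n = 2000
        pc = PointCloud(rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                        np.abs(rng.normal(0, 0.05, n)),
                        np.ones(n, int), np.ones(n, int),
                        np.ones(n, bool))
        assert delineate(pc) == []

    def test_point_order_invariance(self, separable_scene):
        _, _, cloud = separable_scene
        perm = np.random.default_rng(3).permutation(len(cloud))
        shuffled = PointCloud(cloud.x[perm], cloud.y[perm], cloud.z[perm],
                              cloud.return_number[perm], cloud.num_returns[perm],
                              cloud.is_ground[perm])
        a = delineate(cloud)
        b = delineate(shuffled)
        assert len(a) == len(b)
        for ia, ib in zip(a, b):
            assert ia.polygon.equals(ib.polygon)
            assert ia.height == pytest.approx(ib.height)

    def test_every_itc_contains_its_seed(self, separable_scene):
        _, _, cloud = separable_scene
        from shapely.geometry import Point
        for itc in delineate(cloud):
            assert itc.polygon.buffer(1e-9).contains(Point(itc.seed.x, itc.seed.y))
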