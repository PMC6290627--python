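"""Centroid, stretch index, Graham-scan hull, overlap, length/width."""

import itertools

import numpy as np
import pytest
from scipy.spatial import ConvexHull as ScipyHull
from shapely.geometry import Polygon

import pitchmetrics as pm

from conftest import make_dataset, static_dataset


# --- independent O(n^4) hull oracle: a point is a hull vertex iff no
# --- triangle of three other points contains it (boundary included)

def _cross2(u, v):
    return u[0] * v[1] - u[1] * v[0]


def _in_triangle(p, a, b, c, eps=1e-12):
    d1 = _cross2(b - a, p - a)
    d2 = _cross2(c - b, p - b)
    d3 = _cross2(a - c, p - c)
    if abs(_cross2(b - a, c - a)) < eps:  # degenerate triangle
        return False
    return (d1 >= -eps and d2 >= -eps and d3 >= -eps) or (
        d1 <= eps and d2 <= eps and d3 <= eps
    )


def hull_oracle(points):
    pts = np.asarray(points, dtype=float)
    keep = []
    for i in range(len(pts)):
        others = np.delete(pts, i, axis=0)
        covered = any(
            _in_triangle(pts[i], *others[list(tri)])
            for tri in itertools.combinations(range(len(others)), 3)
        )
        if not covered:
            keep.append(pts[i])
    keep = np.asarray(keep)
    center = keep.mean(axis=0)
    order = np.argsort(np.arctan2(keep[:, 1] - center[1], keep[:, 0] - center[0]))
    verts = keep[order]
    return verts, pm.shoelace_area(verts)


class TestCentroid:
    def test_square_symmetry(self):
        ds = static_dataset(
            {"a": (0.0, 0.0), "b": (2.0, 0.0), "c": (0.0, 2.0), "d": (2.0, 2.0)}
        )
        cs = pm.centroid_series(ds, pm.GroupSelection(("a", "b", "c", "d")))
        assert np.allclose(cs.x, 1.0) and np.allclose(cs.y, 1.0)

    def test_two_player_midpoint(self):
        ds = static_dataset({"a": (0.0, 0.0), "b": (4.0, 0.0)})
        cs = pm.centroid_series(ds, pm.GroupSelection(("a", "b")))
        assert np.allclose(cs.x, 2.0) and np.allclose(cs.y, 0.0)

    def test_permutation_invariance(self, square_dataset):
        a = pm.centroid_series(square_dataset, pm.GroupSelection(("p1", "p2", "p3", "p4")))
        b = pm.centroid_series(square_dataset, pm.GroupSelection(("p4", "p2", "p1", "p3")))
        assert np.allclose(a.x, b.x) and np.allclose(a.y, b.y)

    def test_centroid_inside_bounding_box(self, rng):
        pos = {f"p{i}": (rng.uniform(0, 105, 20), rng.uniform(0, 68, 20)) for i in range(5)}
        ds = make_dataset(pos)
        g = pm.GroupSelection(tuple(pos))
        cs = pm.centroid_series(ds, g)
        _, X, Y = ds.pivot(g)
        assert (cs.x >= X.min(axis=1)).all() and (cs.x <= X.max(axis=1)).all()
        assert (cs.y >= Y.min(axis=1)).all() and (cs.y <= Y.max(axis=1)).all()

    def test_missing_player_at_frame_rejected(self, square_dataset):
        frame = square_dataset.frame.drop(index=5)
        ds = pm.PositionalDataset(frame=frame, rate=10.0, pitch=square_dataset.pitch)
        with pytest.raises(pm.ValidationError):
            pm.centroid_series(ds, pm.GroupSelection(("p1", "p2", "p3", "p4")))


class TestRadialDistancesAndStretch:
    def test_square_radial_distances(self, square_dataset, square_group):
        rd = pm.radial_distances(square_dataset, square_group)
        for pid in square_group.player_ids:
            assert np.allclose(rd[f"dist_{pid}_m"], np.sqrt(2.0))

    def test_coincident_players_zero(self):
        ds = static_dataset({"a": (5.0, 5.0), "b": (5.0, 5.0), "c": (5.0, 5.0)})
        rd = pm.radial_distances(ds, pm.GroupSelection(("a", "b", "c")))
        si = pm.stretch_index_series(ds, pm.GroupSelection(("a", "b", "c")))
        assert np.allclose(rd.iloc[:, 1:], 0.0)
        assert np.allclose(si["stretch_index_m"], 0.0)
        assert np.allclose(si["stretch_rate_mps"], 0.0)

    def test_random_config_matches_bruteforce(self, rng):
        pos = {f"p{i}": (rng.uniform(0, 105, 15), rng.uniform(0, 68, 15)) for i in range(6)}
        ds = make_dataset(pos)
        g = pm.GroupSelection(tuple(pos))
        rd = pm.radial_distances(ds, g)
        t, X, Y = ds.pivot(g)
        for k in range(len(t)):
            cx, cy = X[k].mean(), Y[k].mean()
            for j, pid in enumerate(g.player_ids):
                expect = np.hypot(X[k, j] - cx, Y[k, j] - cy)
                assert rd[f"dist_{pid}_m"].iloc[k] == pytest.approx(expect, abs=1e-12)

    def test_square_stretch_index(self, square_dataset, square_group):
        si = pm.stretch_index_series(square_dataset, square_group)
        assert np.allclose(si["stretch_index_m"], np.sqrt(2.0))

    def test_expanding_square_rate_matches_closed_form(self):
        # corners at center +- (t, t): SI(t) = sqrt(2) t, so dSI/dt = sqrt(2)
        t = np.arange(1, 101) / 10.0
        c = 50.0
        ds = make_dataset(
            {
                "a": (c - t, c - t), "b": (c + t, c - t),
                "c": (c - t, c + t), "d": (c + t, c + t),
            }
        )
        si = pm.stretch_index_series(ds, pm.GroupSelection(("a", "b", "c", "d")))
        assert np.allclose(si["stretch_index_m"], np.sqrt(2.0) * t, rtol=1e-9)
        assert np.allclose(si["stretch_rate_mps"], np.sqrt(2.0), rtol=1e-6)


class TestCentroidDistances:
    def test_mirror_groups(self):
        # groups mirror-imaged about the pitch center
        ds = static_dataset(
            {"a1": (40.0, 30.0), "a2": (44.0, 38.0), "b1": (65.0, 38.0), "b2": (61.0, 30.0)}
        )
        inter, _ = pm.centroid_distances(
            ds, pm.GroupSelection(("a1", "a2")), pm.GroupSelection(("b1", "b2"))
        )
        # centroids at (42, 34) and (63, 34): distance 21, twice each
        # centroid's distance to the midpoint (52.5, 34)
        assert np.allclose(inter["centroid_distance_m"], 21.0)

    def test_identical_positions_zero(self):
        ds = static_dataset(
            {"a1": (40.0, 30.0), "a2": (44.0, 38.0), "b1": (40.0, 30.0), "b2": (44.0, 38.0)}
        )
        inter, _ = pm.centroid_distances(
            ds, pm.GroupSelection(("a1", "a2")), pm.GroupSelection(("b1", "b2"))
        )
        assert np.allclose(inter["centroid_distance_m"], 0.0)

    def test_overlapping_groups_rejected(self, square_dataset):
        with pytest.raises(pm.SelectionError):
            pm.centroid_distances(
                square_dataset,
                pm.GroupSelection(("p1", "p2")),
                pm.GroupSelection(("p2", "p3")),
            )

    def test_per_player_distances_match_bruteforce(self, rng):
        pos = {f"p{i}": (rng.uniform(0, 105, 10), rng.uniform(0, 68, 10)) for i in range(6)}
        ds = make_dataset(pos)
        ga = pm.GroupSelection(("p0", "p1", "p2"))
        gb = pm.GroupSelection(("p3", "p4", "p5"))
        _, per = pm.centroid_distances(ds, ga, gb)
        _, Xb, Yb = ds.pivot(gb)
        cbx, cby = Xb.mean(axis=1), Yb.mean(axis=1)
        _, Xa, Ya = ds.pivot(ga)
        for j, pid in enumerate(ga.player_ids):
            expect = np.hypot(Xa[:, j] - cbx, Ya[:, j] - cby)
            assert np.allclose(per[f"dist_{pid}_m"], expect, atol=1e-12)


class TestConvexHull:
    def test_square_with_interior_point(self):
        hull = pm.convex_hull([(0, 0), (2, 0), (2, 2), (0, 2), (1, 1)])
        assert len(hull.vertices) == 4
        assert hull.area == pytest.approx(4.0)
        assert not hull.degenerate

    def test_collinear_points_degenerate(self):
        hull = pm.convex_hull([(0, 0), (1, 1), (2, 2)])
        assert hull.degenerate
        assert hull.area == 0.0

    def test_collinear_edge_point_excluded(self):
        hull = pm.convex_hull([(0, 0), (2, 0), (2, 2), (0, 2), (1, 0)])
        assert len(hull.vertices) == 4
        assert hull.area == pytest.approx(4.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(pm.GroupSizeError):
            pm.convex_hull([(0, 0), (1, 1)])

    def test_vertices_counter_clockwise(self, rng):
        pts = rng.uniform(0, 50, size=(8, 2))
        v = pm.convex_hull(pts).vertices
        signed = 0.5 * (
            np.dot(v[:, 0], np.roll(v[:, 1], -1)) - np.dot(v[:, 1], np.roll(v[:, 0], -1))
        )
        assert signed > 0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 11))
            pts = rng.uniform(0, 105, size=(n, 2)) * np.array([1.0, 68 / 105])
            hull = pm.convex_hull(pts)
            overts, oarea = hull_oracle(pts)
            assert hull.area == pytest.approx(oarea, rel=1e-9, abs=1e-9)
            got = {tuple(np.round(p, 9)) for p in hull.vertices}
            want = {tuple(np.round(p, 9)) for p in overts}
            assert got == want

    def test_matches_scipy_reference(self, rng):
        for _ in range(50):
            pts = rng.uniform(0, 100, size=(int(rng.integers(4, 11)), 2))
            assert pm.convex_hull(pts).area == pytest.approx(
                ScipyHull(pts).volume, rel=1e-12
            )

    def test_interior_point_does_not_change_area(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 100, size=(6, 2))
            hull = pm.convex_hull(pts)
            inside = hull.vertices.mean(axis=0)
            grown = pm.convex_hull(np.vstack([pts, inside]))
            assert grown.area == pytest.approx(hull.area, rel=1e-12)


class TestSurfaceArea:
    def test_static_square_area(self, square_dataset):
        g = pm.GroupSelection(("p1", "p2", "p3", "p4"), min_size=3)
        area = pm.surface_area_series(square_dataset, g)
        assert np.allclose(area["area_m2"], 4.0)

    def test_group_size_enforced(self, square_dataset):
        with pytest.raises(pm.GroupSizeError):
            pm.surface_area_series(square_dataset, pm.GroupSelection(("p1", "p2")))

    def test_uniform_contraction_scales_area_quadratically(self):
        s = np.linspace(1.0, 0.0, 50)
        c = 50.0
        ds = make_dataset(
            {
                "a": (c - 2 * s, c - 2 * s), "b": (c + 2 * s, c - 2 * s),
                "c": (c - 2 * s, c + 2 * s), "d": (c + 2 * s, c + 2 * s),
            }
        )
        area = pm.surface_area_series(ds, pm.GroupSelection(("a", "b", "c", "d"), min_size=3))
        assert np.allclose(area["area_m2"], 16.0 * s**2, atol=1e-9)
        assert (np.diff(area["area_m2"]) <= 1e-12).all()


class TestOverlap:
    @staticmethod
    def _two_group_dataset(points_a, points_b):
        pos = {}
        for i, p in enumerate(points_a):
            pos[f"a{i}"] = p
        for i, p in enumerate(points_b):
            pos[f"b{i}"] = p
        ds = static_dataset(pos, n_frames=3)
        ga = pm.GroupSelection(tuple(k for k in pos if k.startswith("a")), min_size=3)
        gb = pm.GroupSelection(tuple(k for k in pos if k.startswith("b")), min_size=3)
        return ds, ga, gb

    def test_disjoint_hulls_zero(self):
        ds, ga, gb = self._two_group_dataset(
            [(0, 0), (5, 0), (0, 5)], [(20, 20), (25, 20), (20, 25)]
        )
        out = pm.overlap_area_series(ds, ga, gb)
        assert np.allclose(out["overlap_area_m2"], 0.0)

    def test_identical_hulls_full_overlap(self):
        tri = [(10, 10), (20, 10), (15, 18)]
        ds, ga, gb = self._two_group_dataset(tri, tri)
        out = pm.overlap_area_series(ds, ga, gb)
        assert np.allclose(out["overlap_area_m2"], pm.convex_hull(tri).area)

    def test_contained_square(self):
        ds, ga, gb = self._two_group_dataset(
            [(10, 10), (12, 10), (12, 12), (10, 12)],
            [(9, 9), (13, 9), (13, 13), (9, 13)],
        )
        out = pm.overlap_area_series(ds, ga, gb)
        assert np.allclose(out["overlap_area_m2"], 4.0)

    def test_matches_shapely_on_random_hulls(self, rng):
        for _ in range(50):
            pa = rng.uniform(0, 60, size=(5, 2))
            pb = rng.uniform(20, 80, size=(5, 2))
            ha, hb = pm.convex_hull(pa), pm.convex_hull(pb)
            got = pm.shoelace_area(pm.clip_convex(ha.vertices, hb.vertices))
            want = Polygon(ha.vertices).intersection(Polygon(hb.vertices)).area
            assert got == pytest.approx(want, abs=1e-8)
            assert got <= min(ha.area, hb.area) + 1e-9


class TestLengthWidth:
    def test_square(self, square_dataset, square_group):
        lw = pm.length_width_series(square_dataset, square_group)
        assert np.allclose(lw["length_m"], 2.0)
        assert np.allclose(lw["width_m"], 2.0)

    def test_longitudinal_line_has_zero_width(self):
        ds = static_dataset({"a": (10.0, 30.0), "b": (20.0, 30.0), "c": (35.0, 30.0)})
        lw = pm.length_width_series(ds, pm.GroupSelection(("a", "b", "c")))
        assert np.allclose(lw["length_m"], 25.0)
        assert np.allclose(lw["width_m"], 0.0)

    def test_matches_minmax_oracle(self, rng):
        pos = {f"p{i}": (rng.uniform(0, 105, 12), rng.uniform(0, 68, 12)) for i in range(5)}
        ds = make_dataset(pos)
        g = pm.GroupSelection(tuple(pos))
        lw = pm.length_width_series(ds, g)
        _, X, Y = ds.pivot(g)
        assert np.allclose(lw["length_m"], X.max(axis=1) - X.min(axis=1))
        assert np.allclose(lw["width_m"], Y.max(axis=1) - Y.min(axis=1))


class TestGeometryInvariants:
    @staticmethod
    def _metrics(ds, g):
        si = pm.stretch_index_series(ds, g)["stretch_index_m"].to_numpy()
        area = pm.surface_area_series(ds, g)["area_m2"].to_numpy()
        lw = pm.length_width_series(ds, g)
        return si, area, lw["length_m"].to_numpy(), lw["width_m"].to_numpy()

    def _random_group(self, rng, n_frames=8, n_players=6, spread=12.0):
        pos = {
            f"p{i}": (
                40 + rng.uniform(-spread, spread, n_frames),
                30 + rng.uniform(-spread, spread, n_frames),
            )
            for i in range(n_players)
        }
        return pos

    def test_translation_behavior(self, rng):
        pos = self._random_group(rng)
        g = pm.GroupSelection(tuple(pos))
        ds = make_dataset(pos)
        moved = make_dataset({k: (x + 7.0, y - 3.0) for k, (x, y) in pos.items()})
        ca, cb = pm.centroid_series(ds, g), pm.centroid_series(moved, g)
        assert np.allclose(cb.x - ca.x, 7.0) and np.allclose(cb.y - ca.y, -3.0)
        for a, b in zip(self._metrics(ds, g), self._metrics(moved, g)):
            assert np.allclose(a, b, atol=1e-9)

    def test_rotation_behavior(self, rng):
        pos = self._random_group(rng)
        g = pm.GroupSelection(tuple(pos))
        ds = make_dataset(pos)
        th = np.radians(30.0)
        rot = make_dataset(
            {
                k: (
                    40 + np.cos(th) * (x - 40) - np.sin(th) * (y - 30),
                    30 + np.sin(th) * (x - 40) + np.cos(th) * (y - 30),
                )
                for k, (x, y) in pos.items()
            }
        )
        si_a, area_a, len_a, wid_a = self._metrics(ds, g)
        si_b, area_b, len_b, wid_b = self._metrics(rot, g)
        assert np.allclose(si_a, si_b, atol=1e-9)
        assert np.allclose(area_a, area_b, atol=1e-9)
        # length/width are axis-aligned by definition, so rotation changes them
        assert not np.allclose(len_a, len_b, atol=1e-6)

    def test_scaling_behavior(self, rng):
        pos = self._random_group(rng)
        g = pm.GroupSelection(tuple(pos))
        ds = make_dataset(pos)
        t, X, Y = ds.pivot(g)
        cx = X.mean(axis=1, keepdims=True)
        cy = Y.mean(axis=1, keepdims=True)
        s = 1.5
        scaled = make_dataset(
            {
                k: (
                    (cx + s * (X[:, [j]] - cx)).ravel(),
                    (cy + s * (Y[:, [j]] - cy)).ravel(),
                )
                for j, k in enumerate(g.player_ids)
            }
        )
        si_a, area_a, len_a, wid_a = self._metrics(ds, g)
        si_b, area_b, len_b, wid_b = self._metrics(scaled, g)
        assert np.allclose(si_b, s * si_a, rtol=1e-9)
        assert np.allclose(area_b, s**2 * area_a, rtol=1e-9)
        assert np.allclose(len_b, s * len_a, rtol=1e-9)
        assert np.allclose(wid_b, s * wid_a, rtol=1e-9)

    def test_area_bounded_by_length_times_width(self, rng):
        pos = self._random_group(rng, n_frames=20)
        g = pm.GroupSelection(tuple(pos))
        ds = make_dataset(pos)
        _, area, length, width = self._metrics(ds, g)
        assert (area <= length * width + 1e-9).all()


def test_collective_series_area_needs_three(square_dataset):
    with pytest.raises(pm.GroupSizeError, match="3"):
        pm.collective_series(square_dataset, pm.GroupSelection(("p1", "p2")))
    ok = pm.collective_series(
        square_dataset, pm.GroupSelection(("p1", "p2")), include_area=False
    )
    assert "area_m2" not in ok.columns
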