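"""Group-level geometry per frame: centroid, stretch index, convex-hull
surface area and overlap, team length/width.

The centroid (team center / gravity center) is the unweighted mean position
of the selected players. The stretch index is the mean radial distance of
the players to that centroid; its first derivative is the speed at which
the group stretches or compacts. The effective playing space (surface area)
is the area of the convex hull of the players' positions, computed with a
Graham scan — well suited to the at-most-ten points a group contributes per
frame. Team length/width are the max-min spreads along the longitudinal and
transverse pitch axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GroupSizeError, SelectionError
from .positional import GroupSelection, PositionalDataset

_EPS = 1e-12


@dataclass
class HullPolygon:
    """Convex hull with counter-clockwise vertices and shoelace area (m^2).

    ``degenerate`` marks an all-collinear input: the "hull" is the extreme
    segment and the area is exactly 0.
    """

    vertices: np.ndarray
    area: float
    degenerate: bool = False


@dataclass
class CentroidSeries:
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    group: GroupSelection

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "centroid_x_m": self.x, "centroid_y_m": self.y}
        )


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed-area magnitude of a simple polygon (CCW positive)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> HullPolygon:
    """Convex hull of >= 3 planar points via Graham scan.

    Pivot is the lowest-y (then lowest-x) point; remaining points are
    sorted by polar angle around it, collinear ones by distance from the
    pivot. Strict left turns only, so collinear points interior to a hull
    edge are excluded from the vertex list (the area is unaffected).
    All-collinear inputs yield a degenerate hull with area 0.
    """
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if np.asarray(points).reshape(-1, 2).shape[0] < 3:
        raise GroupSizeError("convex hull needs at least 3 points")
    if len(pts) == 1:
        return HullPolygon(vertices=pts, area=0.0, degenerate=True)

    pivot_idx = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    pivot = pts[pivot_idx]
    rest = np.delete(pts, pivot_idx, axis=0)
    d = rest - pivot
    angles = np.arctan2(d[:, 1], d[:, 0])
    dist2 = d[:, 0] ** 2 + d[:, 1] ** 2
    order = np.lexsort((dist2, angles))
    rest = rest[order]

    stack: list[np.ndarray] = [pivot]
    for p in rest:
        while len(stack) >= 2 and _cross(stack[-2], stack[-1], p) <= _EPS:
            stack.pop()
        stack.append(p)
    vertices = np.array(stack)
    if len(vertices) < 3:
        # all points collinear: keep the extreme segment
        lo = pts[np.lexsort((pts[:, 1], pts[:, 0]))[0]]
        hi = pts[np.lexsort((pts[:, 1], pts[:, 0]))[-1]]
        return HullPolygon(vertices=np.array([lo, hi]), area=0.0, degenerate=True)
    return HullPolygon(vertices=vertices, area=shoelace_area(vertices))


def clip_convex(subject: np.ndarray, clip: np.ndarray) -> np.ndarray:
    """Intersection of two convex CCW polygons (Sutherland–Hodgman).

    Each edge of ``clip`` defines a half-plane; ``subject`` is clipped
    against them in turn. Returns the (possibly empty) CCW intersection
    polygon.
    """
    output = [tuple(p) for p in np.asarray(subject, dtype=float)]
    clip = np.asarray(clip, dtype=float)
    n = len(clip)
    for i in range(n):
        if not output:
            return np.empty((0, 2))
        a, b = clip[i], clip[(i + 1) % n]
        inp = output
        output = []
        for j in range(len(inp)):
            cur, prev = inp[j], inp[j - 1]
            cur_in = _cross(a, b, cur) >= -_EPS
            prev_in = _cross(a, b, prev) >= -_EPS
            if cur_in:
                if not prev_in:
                    output.append(_segment_line_intersection(prev, cur, a, b))
                output.append(cur)
            elif prev_in:
                output.append(_segment_line_intersection(prev, cur, a, b))
    return np.asarray(output, dtype=float)


def _segment_line_intersection(p, q, a, b):
    """Intersection of segment pq with the infinite line through a, b."""
    r = (q[0] - p[0], q[1] - p[1])
    s = (b[0] - a[0], b[1] - a[1])
    denom = r[0] * s[1] - r[1] * s[0]
    if abs(denom) < _EPS:
        return q
    t = ((a[0] - p[0]) * s[1] - (a[1] - p[1]) * s[0]) / denom
    return (p[0] + t * r[0], p[1] + t * r[1])


def centroid_series(dataset: PositionalDataset, group: GroupSelection) -> CentroidSeries:
    """Per-frame unweighted mean position of the group members."""
    _require(group, 2, "centroid")
    times, X, Y = dataset.pivot(group)
    return CentroidSeries(times=times, x=X.mean(axis=1), y=Y.mean(axis=1), group=group)


def radial_distances(dataset: PositionalDataset, group: GroupSelection) -> pd.DataFrame:
    """Per-frame Euclidean distance of each member to the group centroid."""
    _require(group, 2, "radial distances")
    times, X, Y = dataset.pivot(group)
    cx = X.mean(axis=1, keepdims=True)
    cy = Y.mean(axis=1, keepdims=True)
    D = np.hypot(X - cx, Y - cy)
    out = {"time_s": times}
    for j, pid in enumerate(group.player_ids):
        out[f"dist_{pid}_m"] = D[:, j]
    return pd.DataFrame(out)


def stretch_index_series(
    dataset: PositionalDataset, group: GroupSelection
) -> pd.DataFrame:
    """Stretch index (mean radial distance to centroid) and its rate.

    The rate is a centered finite difference at interior frames and
    one-sided at the series ends.
    """
    _require(group, 2, "stretch index")
    times, X, Y = dataset.pivot(group)
    cx = X.mean(axis=1, keepdims=True)
    cy = Y.mean(axis=1, keepdims=True)
    si = np.hypot(X - cx, Y - cy).mean(axis=1)
    rate = np.gradient(si, times) if len(times) > 1 else np.zeros_like(si)
    return pd.DataFrame(
        {"time_s": times, "stretch_index_m": si, "stretch_rate_mps": rate}
    )


def centroid_distances(
    dataset: PositionalDataset, group_a: GroupSelection, group_b: GroupSelection
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inter-centroid distance and each A-member's distance to B's centroid.

    Groups must be disjoint (a player cannot sit on both sides).
    """
    overlap = set(group_a.player_ids) & set(group_b.player_ids)
    if overlap:
        raise SelectionError(f"groups overlap on players {sorted(overlap)}")
    ca = centroid_series(dataset, group_a)
    cb = centroid_series(dataset, group_b)
    inter = pd.DataFrame(
        {
            "time_s": ca.times,
            "centroid_distance_m": np.hypot(ca.x - cb.x, ca.y - cb.y),
        }
    )
    times, X, Y = dataset.pivot(group_a)
    out = {"time_s": times}
    for j, pid in enumerate(group_a.player_ids):
        out[f"dist_{pid}_m"] = np.hypot(X[:, j] - cb.x, Y[:, j] - cb.y)
    return inter, pd.DataFrame(out)


def surface_area_series(
    dataset: PositionalDataset, group: GroupSelection
) -> pd.DataFrame:
    """Per-frame convex-hull area of the group, in real field m^2."""
    _require(group, 3, "surface area")
    times, X, Y = dataset.pivot(group)
    areas = np.empty(len(times))
    for i in range(len(times)):
        areas[i] = convex_hull(np.column_stack([X[i], Y[i]])).area
    return pd.DataFrame({"time_s": times, "area_m2": areas})


def overlap_area_series(
    dataset: PositionalDataset, group_a: GroupSelection, group_b: GroupSelection
) -> pd.DataFrame:
    """Per-frame area of the intersection of the two groups' hulls."""
    _require(group_a, 3, "overlap area")
    _require(group_b, 3, "overlap area")
    times, Xa, Ya = dataset.pivot(group_a)
    _, Xb, Yb = dataset.pivot(group_b)
    areas = np.empty(len(times))
    for i in range(len(times)):
        ha = convex_hull(np.column_stack([Xa[i], Ya[i]]))
        hb = convex_hull(np.column_stack([Xb[i], Yb[i]]))
        if ha.degenerate or hb.degenerate:
            areas[i] = 0.0
        else:
            areas[i] = shoelace_area(clip_convex(ha.vertices, hb.vertices))
    return pd.DataFrame({"time_s": times, "overlap_area_m2": areas})


def length_width_series(
    dataset: PositionalDataset, group: GroupSelection
) -> pd.DataFrame:
    """Team length (longitudinal max-min) and width (transverse max-min)."""
    _require(group, 2, "length/width")
    times, X, Y = dataset.pivot(group)
    return pd.DataFrame(
        {
            "time_s": times,
            "length_m": X.max(axis=1) - X.min(axis=1),
            "width_m": Y.max(axis=1) - Y.min(axis=1),
        }
    )


def collective_series(
    dataset: PositionalDataset, group: GroupSelection, include_area: bool = True
) -> pd.DataFrame:
    """One-stop per-frame collective summary for a group.

    Columns: time, centroid, stretch index + rate, length, width and (for
    groups of three or more, unless disabled) hull area.
    """
    _require(group, 2, "collective series")
    if include_area and len(group) < 3:
        raise GroupSizeError(
            f"surface area requires at least 3 players; group has {len(group)} "
            "(pass include_area=False for centroid-only metrics)"
        )
    cen = centroid_series(dataset, group)
    si = stretch_index_series(dataset, group)
    lw = length_width_series(dataset, group)
    out = pd.DataFrame(
        {
            "time_s": cen.times,
            "stretch_index_m": si["stretch_index_m"],
            "stretch_rate_mps": si["stretch_rate_mps"],
            "length_m": lw["length_m"],
            "width_m": lw["width_m"],
            "centroid_x_m": cen.x,
            "centroid_y_m": cen.y,
        }
    )
    if include_area:
        out.insert(3, "area_m2", surface_area_series(dataset, group)["area_m2"])
    return out


def _require(group: GroupSelection, n: int, what: str) -> None:
    if len(group) < n:
        raise GroupSizeError(f"{what} requires at least {n} players, got {len(group)}")
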