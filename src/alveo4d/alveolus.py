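"""Polygon-based model of alveolar expansion.

The inner boundary of a growing alveolus is abstracted as a point cloud
``(t, x, y, z)``.  The cloud is partitioned into one snapshot per distinct
time value, each snapshot is sliced at a fixed plane ``z = Z``, closed
non-self-intersecting point loops are chained in the slice, the
largest-area loop at t = 0 is chosen as the alveolus of interest (and
followed forward in time by centroid proximity), and each loop is fitted
with a simple polygon whose area A (shoelace), perimeter P and ratio
R = A / P are reported over time.  R has units of length and grows with
alveolar expansion; it is an indicator of polygon shape complexity, the
opposite of compactness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "partition_by_time",
    "planar_slice",
    "closed_sets",
    "fit_polygon",
    "polygon_measures",
    "expansion_series",
]


def partition_by_time(cloud: pd.DataFrame) -> list[tuple[float, pd.DataFrame]]:
    """Split a boundary cloud into k snapshots, one per distinct time value,
    in ascending time order.  The union of snapshots is the input cloud."""
    if len(cloud) == 0:
        raise ValueError("boundary cloud is empty")
    if not np.all(np.isfinite(cloud[["t", "x", "y", "z"]].to_numpy())):
        raise ValueError("boundary cloud contains non-finite coordinates")
    return [(float(t), df) for t, df in cloud.groupby("t", sort=True)]


def planar_slice(snapshot: pd.DataFrame, z_level: float, tol: float = 0.5) -> np.ndarray:
    """Points of a snapshot within ``|z - Z| <= tol`` (inclusive), projected
    to the (x, y) plane.  May be empty; callers skip such snapshots."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    sel = np.abs(snapshot["z"].to_numpy() - z_level) <= tol
    return snapshot.loc[sel, ["x", "y"]].to_numpy(dtype=float)


def _chain_loop(points: np.ndarray, eps: float) -> Optional[np.ndarray]:
    """Order the points of one connected component into a closed loop by
    nearest-neighbour chaining from the minimal-x point.

    The chain stops when the nearest unvisited point is farther than the
    chaining radius (a stray interior point that was skipped earlier does
    not invalidate the loop).  None when the walk does not close on its
    start or covers too little of the component.
    """
    n = len(points)
    if n < 3:
        return None
    start = int(np.lexsort((points[:, 1], points[:, 0]))[0])
    remaining = set(range(n))
    remaining.discard(start)
    order = [start]
    while remaining:
        last = points[order[-1]]
        idxs = np.fromiter(remaining, dtype=int)
        dists = np.linalg.norm(points[idxs] - last, axis=1)
        j = int(idxs[np.argmin(dists)])
        if dists.min() > 1.5 * eps:
            break  # next stretch of the walk would leave the boundary
        order.append(j)
        remaining.discard(j)
    if len(order) < max(3, int(0.8 * n)):
        return None
    loop = points[order]
    if np.linalg.norm(loop[-1] - loop[0]) > 1.5 * eps:
        return None
    return loop


def closed_sets(points: np.ndarray, eps: Optional[float] = None) -> list[np.ndarray]:
    """Closed, non-self-intersecting point loops in a planar point set.

    Points are grouped into connected components under ``eps``-neighbour
    chaining (default eps: three times the median nearest-neighbour spacing
    — for a jittered, evenly spaced boundary the largest gap between
    sequential points approaches twice the mean spacing, so a 2x default
    would fragment clean loops); a
    component forms a loop when its chained path closes on itself and the
    resulting polygon is simple.  Loops are returned largest-area first, so
    the first entry is the alveolus of interest.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return []
    tree = cKDTree(points)
    if eps is None:
        nn, _ = tree.query(points, k=2)
        eps = 3.0 * float(np.median(nn[:, 1]))
    if eps <= 0:
        raise ValueError("eps must be positive")
    pairs = tree.query_pairs(eps, output_type="ndarray")
    # connected components via union-find
    parent = np.arange(len(points))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(len(points)):
        comps.setdefault(find(i), []).append(i)

    loops = []
    for members in comps.values():
        if len(members) < 8:
            continue
        loop = _chain_loop(points[members], eps)
        if loop is None:
            continue
        poly = _ShapelyPolygon(loop)
        if not poly.is_valid or poly.area == 0:
            loop = _angular_sort(points[members])
            poly = _ShapelyPolygon(loop)
            if not poly.is_valid or poly.area == 0:
                continue
        loops.append((poly.area, loop))
    loops.sort(key=lambda t: -t[0])
    return [loop for _a, loop in loops]


def _angular_sort(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    ang = np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0])
    return points[np.argsort(ang)]


def fit_polygon(loop: np.ndarray) -> np.ndarray:
    """Order loop points into a simple polygon, counterclockwise.

    Vertices are chained nearest-neighbour from the minimal-x point (ties
    broken by minimal y); if the chained polygon self-intersects, the points
    are re-ordered by angle about their centroid (flagged with a warning).
    Collinear degenerate input (zero area) is rejected.
    """
    loop = np.asarray(loop, dtype=float)
    if len(loop) < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    start = int(np.lexsort((loop[:, 1], loop[:, 0]))[0])
    remaining = list(range(len(loop)))
    remaining.remove(start)
    order = [start]
    while remaining:
        last = loop[order[-1]]
        dists = np.linalg.norm(loop[remaining] - last, axis=1)
        j = remaining[int(np.argmin(dists))]
        order.append(j)
        remaining.remove(j)
    poly = loop[order]
    if not _ShapelyPolygon(poly).is_valid:
        warnings.warn("nearest-neighbour chain self-intersects; falling back to angular sort",
                      stacklevel=2)
        poly = _angular_sort(loop)
    shp = _ShapelyPolygon(poly)
    if shp.area == 0 or not shp.is_valid:
        raise ValueError("degenerate polygon (zero area or self-intersecting)")
    # normalise orientation to counterclockwise (positive shoelace sum)
    x, y = poly[:, 0], poly[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if signed < 0:
        poly = poly[::-1]
    return poly


def polygon_measures(polygon: np.ndarray) -> tuple[float, float, float]:
    """Area (shoelace), perimeter (closed vertex chain) and ratio R = A/P."""
    polygon = np.asarray(polygon, dtype=float)
    if len(polygon) < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    x, y = polygon[:, 0], polygon[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    if area == 0:
        raise ValueError("degenerate polygon with zero area")
    perimeter = float(np.linalg.norm(np.diff(np.vstack([polygon, polygon[:1]]), axis=0), axis=1).sum())
    return area, perimeter, area / perimeter


def expansion_series(
    cloud: pd.DataFrame,
    z_level: float,
    eps: Optional[float] = None,
    tol: float = 0.5,
    match_gate: float = 10.0,
) -> pd.DataFrame:
    """Area/perimeter/complexity time series of the alveolus of interest.

    Composes the pipeline: partition by time, slice at ``z = Z``, chain
    closed loops, select the largest-area loop of the t = 0 snapshot, match
    it forward in time by centroid proximity (``match_gate`` μm), fit a
    polygon per snapshot and measure (A, P, R).  Snapshots with no loop (or
    no match) are recorded as gaps (NaN rows, ``flagged`` True).
    """
    rows = []
    reference_centroid = None
    for t, snapshot in partition_by_time(cloud):
        points = planar_slice(snapshot, z_level, tol)
        loops = closed_sets(points, eps) if len(points) else []
        chosen = None
        if loops:
            if reference_centroid is None:
                chosen = loops[0]  # largest interior area at t = 0
            else:
                best = match_gate
                for loop in loops:
                    d = float(np.linalg.norm(loop.mean(axis=0) - reference_centroid))
                    if d < best:
                        chosen, best = loop, d
        if chosen is None:
            warnings.warn(f"no closed boundary loop at t={t}; recording gap", stacklevel=2)
            rows.append(dict(t=t, A=np.nan, P=np.nan, R=np.nan, flagged=True))
            continue
        reference_centroid = chosen.mean(axis=0)
        polygon = fit_polygon(chosen)
        area, perimeter, ratio = polygon_measures(polygon)
        rows.append(dict(t=t, A=area, P=perimeter, R=ratio, flagged=False))
    return pd.DataFrame(rows)
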