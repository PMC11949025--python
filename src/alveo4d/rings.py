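"""Mesenchymal ring detection and contraction quantification.

Alveolar myofibroblasts form closed ring structures of 3-5 cells through
which epithelial cells extrude; what looks like a free-standing "septal tip"
in a single optical plane is a section through such a ring.  This module
finds ring-like loops in a binary mesenchymal mask by skeletonizing it,
pruning spur branches, and reporting the closed skeleton cycles whose
equivalent-circle diameter falls in a configurable band and whose points are
nearly coplanar.  Ring diameter is defined from the enclosed planar area,
``d = 2 sqrt(A / pi)``, which is robust to non-circular ring shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .skelgraph import prune_spurs, skeleton_graph

__all__ = [
    "Ring",
    "detect_rings",
    "ring_series",
    "diameter_series",
    "contraction_slope",
    "ring_density",
]


@dataclass
class Ring:
    """A closed mesenchymal loop: best-fit plane, equivalent-circle diameter
    from the enclosed planar area, and the member-cell count when a label
    volume is supplied."""

    ring_id: int
    centroid: np.ndarray  # (3,) μm zyx
    normal: np.ndarray  # (3,) unit
    diameter: float  # μm
    area: float  # μm², enclosed planar area
    members: int  # distinct cell labels on the loop (0 if unknown)
    voxels: np.ndarray  # (n, 3) loop voxel indices


def _fit_plane(points: np.ndarray):
    """Least-squares plane through points: (centroid, unit normal, rms residual)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    resid = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal, resid


def _loop_area(points: np.ndarray, centroid: np.ndarray, normal: np.ndarray) -> float:
    """Planar area enclosed by a loop: project onto the plane, order by
    angle about the centroid, and apply the shoelace formula."""
    ref = np.array([0.0, 1.0, 0.0]) if abs(normal[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    centered = points - centroid
    u, v = centered @ e1, centered @ e2
    order = np.argsort(np.arctan2(v, u))
    u, v = u[order], v[order]
    return 0.5 * abs(float(np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1))))


def _component_cycles(g: nx.Graph) -> list:
    """Independent cycles of a skeleton component, as node lists.

    Uses the unweighted cycle basis; tiny basis cycles from residual
    skeleton thickness are filtered downstream by the diameter band.
    """
    cycles = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        cycles.extend(nx.cycle_basis(nx.Graph(sub)))
    return cycles


def detect_rings(
    mesenchymal_mask: np.ndarray,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    min_diameter: float = 20.0,
    max_diameter: float = 120.0,
    labels: Optional[np.ndarray] = None,
    planarity_tol: float = 0.2,
    spur_length: float = 3.0,
) -> list[Ring]:
    """Detect closed ring structures in a 3-D binary mesenchymal mask.

    The mask is skeletonized, spurs below ``spur_length`` μm are pruned, and
    each independent skeleton cycle is kept if its equivalent-circle
    diameter lies in ``[min_diameter, max_diameter]`` and its rms planarity
    residual is below ``planarity_tol`` times the diameter.  When ``labels``
    is given (a cell label volume), each ring reports the number of distinct
    labels its loop passes through.  An empty mask yields an empty list.
    """
    mask = np.asarray(mesenchymal_mask).astype(bool)
    if not mask.any():
        return []
    vox = np.asarray(voxel_size, dtype=float)
    g = prune_spurs(skeleton_graph(mask, voxel_size), min_length=spur_length)
    rings: list[Ring] = []
    for cycle in _component_cycles(g):
        if len(cycle) < 8:
            continue
        voxels = np.asarray(cycle)
        pts = voxels * vox
        centroid, normal, resid = _fit_plane(pts)
        area = _loop_area(pts, centroid, normal)
        diameter = 2.0 * np.sqrt(area / np.pi)
        if not (min_diameter <= diameter <= max_diameter):
            continue
        if resid > planarity_tol * diameter:
            continue
        members = 0
        if labels is not None:
            hit = set()
            lab = np.asarray(labels)
            for vz, vy, vx in voxels:
                lo = np.maximum([vz - 1, vy - 1, vx - 1], 0)
                patch = lab[lo[0]: vz + 2, lo[1]: vy + 2, lo[2]: vx + 2]
                hit.update(np.unique(patch[patch > 0]).tolist())
            members = len(hit)
        rings.append(
            Ring(len(rings), centroid, normal, float(diameter), float(area),
                 members, voxels)
        )
    # deduplicate cycles that describe the same ring (shared centroid)
    kept: list[Ring] = []
    for ring in sorted(rings, key=lambda r: -r.area):
        if all(
            np.linalg.norm(ring.centroid - k.centroid) > 0.5 * min(ring.diameter, k.diameter)
            for k in kept
        ):
            kept.append(ring)
    for i, ring in enumerate(kept):
        ring.ring_id = i
    return kept


def ring_series(
    masks: Sequence[np.ndarray],
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    frame_interval: float = 1.0,
    match_gate: float = 10.0,
    **detect_kwargs,
) -> pd.DataFrame:
    """Detect rings per frame and match them over time by centroid proximity.

    Returns a table (ring_id, frame, t, d, area, m, cz, cy, cx).  A ring
    lost for one frame terminates its series (truncated, not interpolated).
    """
    rows = []
    previous: dict[int, np.ndarray] = {}
    next_id = 0
    for t, mask in enumerate(masks):
        found = detect_rings(mask, voxel_size=voxel_size, **detect_kwargs)
        current: dict[int, np.ndarray] = {}
        for ring in found:
            assigned = None
            best = match_gate
            for rid, c in previous.items():
                d = float(np.linalg.norm(ring.centroid - c))
                if d < best and rid not in current:
                    assigned, best = rid, d
            if assigned is None:
                assigned = next_id
                next_id += 1
            current[assigned] = ring.centroid
            rows.append(
                dict(ring_id=assigned, frame=t, t=t * frame_interval,
                     d=ring.diameter, area=ring.area, m=ring.members,
                     cz=ring.centroid[0], cy=ring.centroid[1], cx=ring.centroid[2])
            )
        previous = current
    return pd.DataFrame(rows)


def diameter_series(series: pd.DataFrame, ring_id: int) -> pd.DataFrame:
    """The (t, d) series of one matched ring."""
    sub = series[series.ring_id == ring_id].sort_values("frame")
    return sub[["t", "d"]].reset_index(drop=True)


def contraction_slope(series: pd.DataFrame, ring_id: Optional[int] = None) -> float:
    """Least-squares slope of ring diameter vs time (μm/h).

    With ``ring_id`` None, the slope is fitted on all rings jointly after
    removing each ring's mean diameter (a shared-contraction estimate).
    """
    if ring_id is not None:
        sub = diameter_series(series, ring_id)
        t, d = sub["t"].to_numpy(), sub["d"].to_numpy()
    else:
        t_parts, d_parts = [], []
        for rid, sub in series.groupby("ring_id"):
            t_parts.append(sub["t"].to_numpy())
            d_parts.append(sub["d"].to_numpy() - sub["d"].mean())
        t = np.concatenate(t_parts)
        d = np.concatenate(d_parts)
        t = t - t.mean()
    if len(t) < 2:
        return float("nan")
    return float(np.polyfit(t, d, 1)[0])


def ring_density(n_rings: int, field_volume_um3: float) -> float:
    """Rings per 10^6 μm³ of imaged tissue."""
    if field_volume_um3 <= 0:
        raise ValueError("field volume must be positive")
    return 1e6 * n_rings / field_volume_um3
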