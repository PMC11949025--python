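"""Ground-truthed synthetic 4D alveologenesis scenes.

Real multi-day light-sheet movies of developing lung slices are enormous and
not redistributable, so every analysis stage in this package is exercised
against synthetic scenes with known ground truth.  A scene emulates the
cellular dynamics of early postnatal alveologenesis:

* membrane-labelled epithelial cells that cluster at mesenchymal rings,
  extrude 60-100 μm along the ring normal, and flatten from round to
  extremely thin over ~42 hours, with a configurable fraction of the
  population undergoing the transition asynchronously;
* mesenchymal rings of 3-5 cells that contract slowly over days;
* an endothelial filament network rendered as tubes;
* raw-acquisition artifacts of oblique-plane light-sheet imaging: shear
  (skew) along the scan axis, slow frame-to-frame drift, and Poisson +
  Gaussian noise.

Everything is bit-reproducible for a fixed seed, and the generator returns
the exact trajectories, shape schedules, ring diameters, drift walk and
network topology it planted, so each downstream stage can be validated by
round trip against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import DEFAULT_CHANNELS, Volume4D
from .morphometrics import ShapeSeries, ellipsoid_sphericity
from .tracking import Track

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "build_scene",
    "render_channel",
    "render_frame",
    "render_movie",
    "render_labels",
    "degrade_acquisition",
    "sphericity_schedule",
    "sphericity_trace",
    "alveolus_cloud",
    "PSI_FLAT",
    "FLAT_ASPECT",
]

MOTILITY_MODES = ("control", "wnt_activated", "wnt_inhibited", "mlck_inhibited")

#: Aspect ratio of the fully flattened cell relative to the round state.
#: Semi-axes are rescaled per frame so cell volume is conserved exactly,
#: leaving sphericity a function of aspect only.
FLAT_ASPECT = (3.0, 3.0, 0.25)

#: Analytic Wadell sphericity of the fully flattened aspect (~0.373).
PSI_FLAT = ellipsoid_sphericity(FLAT_ASPECT)

# Aspect path from sphere to flat, parameterised so that sphericity declines
# *linearly* in time over the flattening window (matching the roughly steady
# single-cell decline seen in live imaging).  The inversion table maps a
# target sphericity onto the interpolation parameter s of the raw path
# (1+2s, 1+2s, 1-0.75s).
_S_GRID = np.linspace(0.0, 1.0, 257)
_PSI_GRID = np.array(
    [ellipsoid_sphericity((1 + 2 * s, 1 + 2 * s, 1 - 0.75 * s)) for s in _S_GRID]
)


def _aspect_for_psi(psi: np.ndarray) -> np.ndarray:
    """Volume-normalised semi-axis aspect triplet reaching a target sphericity."""
    s = np.interp(np.asarray(psi), _PSI_GRID[::-1], _S_GRID[::-1])
    a = 1.0 + 2.0 * s
    c = 1.0 - 0.75 * s
    scale = (a * a * c) ** (-1.0 / 3.0)  # conserve volume
    return np.stack([a * scale, a * scale, c * scale], axis=-1)


@dataclass
class SceneConfig:
    """Parameters of a synthetic alveologenesis scene.

    Defaults are desk-scale: an isotropic 1 μm voxel grid (the instrument's
    0.45 μm scan step is supported but not default) and a small field.  The
    biological defaults follow the imaged tissue: flattening lasts 42 h,
    extruding somata displace 60-100 μm, rings hold 3-5 cells, and the P14
    flattening fraction is 24%.  The ring contraction rate is not quantified
    by imaging; 0.1 μm/h is a placeholder default.
    """

    field_size: tuple[float, float, float] = (96.0, 96.0, 48.0)  # (x, y, z) μm
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (dz, dy, dx) μm
    frame_interval: float = 1.0  # hours
    n_frames: int = 12
    n_rings: int = 3
    cells_per_ring: tuple[int, int] = (3, 5)
    ring_diameter_0: float = 36.0  # μm
    min_ring_diameter: float = 8.0  # μm, contraction floor
    contraction_rate: float = 0.1  # μm/h (placeholder; not quantified in vivo)
    n_epithelial: int = 20
    flatten_fraction: float = 0.24
    flatten_duration: float = 42.0  # hours
    extrusion_range: tuple[float, float] = (60.0, 100.0)  # μm
    motility_mode: str = "control"
    mlck_switch_time: float = 4.0  # hours; contraction/motion arrest after this
    noise: tuple[float, float] = (0.0, 0.0)  # (gaussian_sd, poisson_scale)
    skew_angle: float = 0.0  # degrees
    drift_sd: float = 0.0  # voxels / frame
    seed: int = 0
    # rendering / realism knobs
    cell_radius_range: tuple[float, float] = (4.0, 5.5)  # μm epithelial soma
    nucleus_radius: float = 2.5  # μm
    mesenchymal_width: float = 2.5  # μm ring-cell half thickness
    vessel_radius: float = 2.0  # μm
    n_vessel_nodes: int = 10
    jitter_sd: float = 0.12  # μm Brownian soma jitter per frame
    min_separation: float = 9.0  # μm between epithelial somata at t=0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if any(e <= 0 for e in self.field_size) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("field and voxel extents must be positive")
        # field extents are (x, y, z); voxels are (dz, dy, dx)
        for extent, vox in zip(self.field_size, self.voxel_size[::-1]):
            if extent / vox < 4:
                raise ValueError("field must span at least 4 voxels per axis")
        if not (0.0 <= self.flatten_fraction <= 1.0):
            raise ValueError("flatten_fraction must lie in [0, 1]")
        lo, hi = self.extrusion_range
        if lo > hi:
            raise ValueError("extrusion_range must satisfy min <= max")
        mlo, mhi = self.cells_per_ring
        if not (3 <= mlo <= mhi):
            raise ValueError("cells_per_ring bounds must satisfy 3 <= lo <= hi")
        if self.contraction_rate < 0:
            raise ValueError("contraction_rate must be >= 0")
        if self.motility_mode not in MOTILITY_MODES:
            raise ValueError(f"motility_mode must be one of {MOTILITY_MODES}")
        if abs(self.skew_angle) >= 90:
            raise ValueError("|skew_angle| must be < 90 degrees")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Voxel grid (nz, ny, nx)."""
        fx, fy, fz = self.field_size
        dz, dy, dx = self.voxel_size
        return (int(round(fz / dz)), int(round(fy / dy)), int(round(fx / dx)))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @classmethod
    def p14_preset(cls, **overrides) -> "SceneConfig":
        """Preset emulating a P14 slice population: 200 traced epithelial
        cells in a full imaging ROI (350 x 220 x 80 μm), 24% flattening, a
        movie long enough for late-onset events to complete."""
        params = dict(
            field_size=(350.0, 220.0, 80.0),
            n_epithelial=200,
            flatten_fraction=0.24,
            n_frames=100,
            frame_interval=1.0,
            n_rings=6,
        )
        params.update(overrides)
        return cls(**params)


def _rotation_to(z_target: np.ndarray) -> np.ndarray:
    """Rotation matrix (zyx convention) mapping the local z axis onto
    ``z_target`` (unit vector, zyx components)."""
    z = np.asarray(z_target, dtype=float)
    z = z / np.linalg.norm(z)
    ref = np.array([0.0, 1.0, 0.0]) if abs(z[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    x = np.cross(z, ref)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    # columns are the images of the local basis vectors (z, y, x local)
    return np.stack([z, y, x], axis=1)


@dataclass
class CellTruth:
    cell_id: int
    kind: str  # "epithelial" | "mesenchymal"
    ring_id: int  # -1 when unassigned
    flattening: bool
    onset: float  # hours
    duration: float  # hours
    delta: float  # planted extrusion distance μm (0 if none)
    radius: float  # round-state equivalent radius μm
    centroids: np.ndarray  # (T, 3) μm zyx
    axes: np.ndarray  # (T, 3) semi-axes μm
    orient: np.ndarray  # (T, 3, 3) rotation matrices


@dataclass
class RingTruth:
    ring_id: int
    center: np.ndarray  # (3,) μm zyx
    normal: np.ndarray  # (3,) unit zyx
    members: tuple  # member cell ids
    diameter: np.ndarray  # (T,) μm
    member_phases: np.ndarray = None  # (m, T) radians, position along the ring
    width: float = 2.5  # μm, cell half-thickness around the ring circle


@dataclass
class GroundTruth:
    """Everything the generator planted, for round-trip validation."""

    config: SceneConfig
    cells: list
    rings: list
    network_nodes: np.ndarray  # (N, 3) μm zyx
    network_edges: list  # [(i, j), ...]
    drift: np.ndarray  # (T, 3) voxels, zeros until degradation is applied

    @property
    def times(self) -> np.ndarray:
        return self.config.times

    def epithelial(self) -> list:
        return [c for c in self.cells if c.kind == "epithelial"]

    def sphericity_series(self, cell: CellTruth) -> np.ndarray:
        """Analytic per-frame sphericity of a cell's planted ellipsoid."""
        return np.array([ellipsoid_sphericity(ax) for ax in cell.axes])

    def shape_series(self, noise_sd: float = 0.0, seed: int = 0) -> list:
        """Analytic :class:`ShapeSeries` per epithelial cell, optionally with
        Gaussian measurement noise on sphericity."""
        rng = np.random.default_rng(seed)
        out = []
        for c in self.epithelial():
            psi = self.sphericity_series(c)
            if noise_sd > 0:
                psi = psi + rng.normal(0.0, noise_sd, psi.shape)
            out.append(
                ShapeSeries(
                    cell_id=c.cell_id,
                    times=self.times,
                    psi=psi,
                    centroids=c.centroids,
                )
            )
        return out

    def tracks(self) -> list:
        """Ground-truth centroid tracks (one per cell, id = cell id)."""
        frames = np.arange(self.config.n_frames)
        return [
            Track(c.cell_id, frames, c.centroids, times=self.times)
            for c in self.cells
        ]

    def to_tables(self) -> dict:
        """Ground truth as flat tables (cells, rings, drift, network)."""
        rows = []
        for c in self.cells:
            for t in range(self.config.n_frames):
                rows.append(
                    dict(
                        cell_id=c.cell_id,
                        kind=c.kind,
                        ring_id=c.ring_id,
                        flattening=c.flattening,
                        frame=t,
                        z=c.centroids[t, 0],
                        y=c.centroids[t, 1],
                        x=c.centroids[t, 2],
                        ax_a=c.axes[t, 0],
                        ax_b=c.axes[t, 1],
                        ax_c=c.axes[t, 2],
                    )
                )
        cells = pd.DataFrame(rows)
        rings = pd.DataFrame(
            [
                dict(ring_id=r.ring_id, frame=t, diameter=r.diameter[t],
                     cz=r.center[0], cy=r.center[1], cx=r.center[2],
                     members=len(r.members))
                for r in self.rings
                for t in range(self.config.n_frames)
            ]
        )
        drift = pd.DataFrame(self.drift, columns=["dz", "dy", "dx"])
        drift.insert(0, "frame", np.arange(len(self.drift)))
        network = pd.DataFrame(
            [
                dict(edge_id=k, node_a=i, node_b=j,
                     az=self.network_nodes[i, 0], ay=self.network_nodes[i, 1],
                     ax=self.network_nodes[i, 2], bz=self.network_nodes[j, 0],
                     by=self.network_nodes[j, 1], bx=self.network_nodes[j, 2])
                for k, (i, j) in enumerate(self.network_edges)
            ]
        )
        return {"cells": cells, "rings": rings, "drift": drift, "network": network}


def sphericity_schedule(
    times: np.ndarray, onset: float, duration: float, psi_flat: float = PSI_FLAT
) -> np.ndarray:
    """Planted sphericity time course of one flattening cell: plateau at 1
    until onset, linear decline to ``psi_flat`` over ``duration`` hours, then
    a flat plateau."""
    u = np.clip((np.asarray(times, dtype=float) - onset) / duration, 0.0, 1.0)
    return 1.0 + u * (psi_flat - 1.0)


def sphericity_trace(
    duration: float = 42.0,
    onset: float = 20.0,
    n_frames: int = 100,
    frame_interval: float = 1.0,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> ShapeSeries:
    """A single-cell synthetic sphericity trace with measurement noise, the
    minimal input for validating the flattening-event detector."""
    times = np.arange(n_frames) * frame_interval
    psi = sphericity_schedule(times, onset, duration)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        psi = psi + rng.normal(0.0, noise_sd, psi.shape)
    return ShapeSeries(cell_id=0, times=times, psi=psi)


def _sample_separated(rng, n, lo, hi, min_sep, max_tries=20000):
    """Rejection-sample ``n`` points in the box [lo, hi] (zyx μm) with a
    minimum pairwise separation, relaxing the separation if the box is too
    crowded."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    pts: list[np.ndarray] = []
    sep = float(min_sep)
    tries = 0
    while len(pts) < n:
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= sep for q in pts):
            pts.append(p)
        tries += 1
        if tries > max_tries:
            sep *= 0.8
            tries = 0
    return np.asarray(pts)


def build_scene(config: SceneConfig) -> GroundTruth:
    """Plant a full scene: rings, epithelial and mesenchymal cells with
    per-frame poses and shapes, and an endothelial network.

    Deterministic for a fixed seed.  Exactly ``round(f * n_epithelial)``
    epithelial cells are flagged as flattening; each draws an extrusion
    distance uniformly from the configured range, directed along its ring's
    plane normal, with onset uniform over the first half of the movie.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_frames
    times = cfg.times
    fx, fy, fz = cfg.field_size
    box_hi = np.array([fz, fy, fx])  # zyx

    mode = cfg.motility_mode
    switch = cfg.mlck_switch_time

    # --- rings ---------------------------------------------------------
    r0 = cfg.ring_diameter_0 / 2.0
    margin = min(r0 + 4.0, min(box_hi) / 2.0 - 1.0)
    ring_centers = _sample_separated(
        rng, cfg.n_rings, [margin] * 3, box_hi - margin,
        min_sep=cfg.ring_diameter_0 + 12.0,
    )
    rings = []
    mes_cells = []
    cell_id = 0
    for rid in range(cfg.n_rings):
        center = ring_centers[rid]
        # keep rings roughly in-plane for thin fields: tilt <= ~30 deg
        tilt = rng.uniform(0.0, 0.5)
        azim = rng.uniform(0.0, 2 * math.pi)
        normal = np.array(
            [math.cos(tilt), math.sin(tilt) * math.sin(azim), math.sin(tilt) * math.cos(azim)]
        )
        m = int(rng.integers(cfg.cells_per_ring[0], cfg.cells_per_ring[1] + 1))
        if mode == "mlck_inhibited":
            eff_t = np.minimum(times, switch)
        else:
            eff_t = times
        diam = np.maximum(
            cfg.ring_diameter_0 - cfg.contraction_rate * eff_t, cfg.min_ring_diameter
        )
        R = _rotation_to(normal)
        e1, e2 = R[:, 1], R[:, 2]  # in-plane basis
        phase = rng.uniform(0.0, 2 * math.pi)
        # slow migration of cells around the scaffold
        omega = rng.normal(0.0, 0.01)  # rad/h
        member_ids = []
        phases = np.empty((m, T))
        w = cfg.mesenchymal_width
        for j in range(m):
            theta = phase + 2 * math.pi * j / m + omega * eff_t
            phases[j] = theta
            radius = diam / 2.0
            centroids = (
                center[None, :]
                + radius[:, None] * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
            )
            # each cell wraps its arc of the ring: record the arc extent as the
            # tangential semi-axis, widths fixed
            a_tan = (math.pi / m) * diam / 2.0
            axes = np.stack([a_tan, np.full(T, w), np.full(T, w)], axis=1)
            orient = np.empty((T, 3, 3))
            for t in range(T):
                tangent = -np.sin(theta[t]) * e1 + np.cos(theta[t]) * e2
                Rt = np.stack([tangent, np.cross(normal, tangent), normal], axis=1)
                orient[t] = Rt
            mes_cells.append(
                CellTruth(
                    cell_id, "mesenchymal", rid, False, 0.0, 0.0, 0.0,
                    float(w), centroids, axes, orient,
                )
            )
            member_ids.append(cell_id)
            cell_id += 1
        rings.append(
            RingTruth(rid, center, normal, tuple(member_ids), diam, phases, w)
        )

    # --- epithelial cells ----------------------------------------------
    n_epi = cfg.n_epithelial
    n_flat = int(round(cfg.flatten_fraction * n_epi))
    flat_flags = np.zeros(n_epi, dtype=bool)
    flat_flags[:n_flat] = True

    pad = 6.0
    positions = _sample_separated(
        rng, n_epi, [pad] * 3, box_hi - pad, cfg.min_separation
    )
    # flattening cells start clustered near their assigned ring, keeping
    # somata separated so nuclei stay individually resolvable
    sep = min(cfg.min_separation, 2.0 * cfg.nucleus_radius + 1.0)
    for i in range(n_flat):
        ring = rings[i % cfg.n_rings] if cfg.n_rings else None
        if ring is None:
            continue
        R = _rotation_to(ring.normal)
        for attempt in range(200):
            rad = rng.uniform(0.0, max(cfg.ring_diameter_0 / 4.0, 2.0))
            ang = rng.uniform(0.0, 2 * math.pi)
            depth = rng.uniform(1.0, 4.0)
            p = np.clip(
                ring.center
                + rad * (math.cos(ang) * R[:, 1] + math.sin(ang) * R[:, 2])
                - depth * ring.normal,
                pad, box_hi - pad,
            )
            others = np.delete(positions, i, axis=0)
            if np.min(np.linalg.norm(others - p, axis=1)) >= sep:
                positions[i] = p
                break
        else:
            positions[i] = p  # crowded ring: accept the last draw

    onsets = rng.uniform(0.0, times[-1] / 2.0, size=n_epi)
    deltas = rng.uniform(*cfg.extrusion_range, size=n_epi)
    radii = rng.uniform(*cfg.cell_radius_range, size=n_epi)
    # alveologenesis events are temporally concurrent within a ring: cells
    # extruding through the same ring share its event onset (small stagger)
    if cfg.n_rings:
        ring_onsets = rng.uniform(0.0, times[-1] / 2.0, size=cfg.n_rings)
        for i in range(n_flat):
            onsets[i] = np.clip(
                ring_onsets[i % cfg.n_rings] + rng.normal(0.0, 3.0),
                0.0, times[-1] / 2.0,
            )

    epi_cells = []
    for i in range(n_epi):
        flattening = bool(flat_flags[i])
        ring = rings[i % cfg.n_rings] if (flattening and cfg.n_rings) else None
        direction = ring.normal if ring is not None else np.array([1.0, 0.0, 0.0])
        onset, delta, a0 = float(onsets[i]), float(deltas[i]), float(radii[i])

        jitter = np.vstack(
            [np.zeros(3), rng.normal(0.0, cfg.jitter_sd, (T - 1, 3))]
        ).cumsum(axis=0)

        if mode == "control" or mode == "mlck_inhibited":
            eff_t = np.minimum(times, switch) if mode == "mlck_inhibited" else times
            u = np.clip((eff_t - onset) / cfg.flatten_duration, 0.0, 1.0)
            directed = (delta * u)[:, None] * direction[None, :] if flattening else 0.0
            if mode == "mlck_inhibited":
                jit = jitter.copy()
                frozen = times > switch
                if frozen.any():
                    jit[frozen] = jit[~frozen][-1] if (~frozen).any() else 0.0
                jitter = jit
            centroids = positions[i][None, :] + directed + jitter
            psi = (
                sphericity_schedule(eff_t, onset, cfg.flatten_duration)
                if flattening
                else np.ones(T)
            )
        elif mode == "wnt_activated":
            # fast oscillatory, low-processivity movement; no completed
            # flattening (cells revert without differentiating)
            amp = rng.uniform(4.0, 8.0)
            period = rng.uniform(3.0, 6.0)
            phase = rng.uniform(0.0, 2 * math.pi)
            osc_dir = rng.normal(size=3)
            osc_dir /= np.linalg.norm(osc_dir)
            osc = amp * np.sin(2 * math.pi * times / period + phase)
            centroids = positions[i][None, :] + osc[:, None] * osc_dir[None, :] + 2.0 * jitter
            psi = np.ones(T)
        else:  # wnt_inhibited: little to no movement, no flattening
            centroids = positions[i][None, :] + 0.1 * jitter
            psi = np.ones(T)

        aspect = _aspect_for_psi(psi)
        axes = aspect * a0
        orient = np.repeat(_rotation_to(direction)[None], T, axis=0)
        epi_cells.append(
            CellTruth(
                cell_id, "epithelial", (ring.ring_id if ring is not None else -1),
                flattening, onset, cfg.flatten_duration,
                (delta if flattening else 0.0), a0, centroids, axes, orient,
            )
        )
        cell_id += 1

    # --- endothelial network -------------------------------------------
    nodes = _sample_separated(
        rng, cfg.n_vessel_nodes, [pad] * 3, box_hi - pad, min_sep=18.0
    )

    def _seg_clearance(a0, a1, b0, b1, n_samples=24):
        # min distance from sampled points of segment a to segment b
        ts = np.linspace(0.0, 1.0, n_samples)[:, None]
        pts = a0 + ts * (a1 - a0)
        v = b1 - b0
        L2 = float(v @ v)
        tproj = np.clip((pts - b0) @ v / L2, 0.0, 1.0) if L2 > 0 else np.zeros(len(pts))
        closest = b0 + tproj[:, None] * v
        return float(np.linalg.norm(pts - closest, axis=1).min())

    # a Euclidean minimum spanning tree gives a branched, triangle-free
    # filament network whose junctions the skeleton can recover one-to-one;
    # edges whose tubes would brush a non-adjacent tube are dropped
    edges: list[tuple[int, int]] = []
    min_clear = 2.0 * cfg.vessel_radius + 2.0
    if len(nodes) >= 2:
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import cdist

        mst = minimum_spanning_tree(cdist(nodes, nodes)).tocoo()
        candidates = sorted(
            ((min(int(i), int(j)), max(int(i), int(j)), float(w))
             for i, j, w in zip(mst.row, mst.col, mst.data)),
            key=lambda e: e[2],
        )
        for i, j, _w in candidates:
            ok = True
            for a, b in edges:
                if {a, b} & {i, j}:
                    continue
                if _seg_clearance(nodes[i], nodes[j], nodes[a], nodes[b]) < min_clear:
                    ok = False
                    break
            if ok:
                edges.append((i, j))
    network_edges = sorted(edges)

    return GroundTruth(
        config=cfg,
        cells=mes_cells + epi_cells,
        rings=rings,
        network_nodes=nodes,
        network_edges=network_edges,
        drift=np.zeros((T, 3)),
    )


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _paint_ellipsoid(img, center, axes, orient, voxel, shell, interior,
                     q_in=0.75, q_out=1.05):
    """Draw an ellipsoidal membrane shell (value ``shell`` on the rim,
    ``interior`` inside) into ``img`` (zyx), taking the maximum with existing
    content.  Bounding-box rasterisation keeps this fast."""
    voxel = np.asarray(voxel, dtype=float)
    rmax = float(np.max(axes)) * q_out + float(voxel.max())
    lo = np.maximum(np.floor((center - rmax) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((center + rmax) / voxel).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[k], hi[k]) * voxel[k] - center[k] for k in range(3)),
        indexing="ij",
    )
    d = np.stack([zz, yy, xx], axis=-1) @ orient  # into local frame
    q = np.sqrt(np.sum((d / np.asarray(axes)) ** 2, axis=-1))
    patch = np.where(q <= q_in, interior, 0.0)
    patch = np.where((q > q_in) & (q <= q_out), shell, patch)
    sl = tuple(slice(lo[k], hi[k]) for k in range(3))
    np.maximum(img[sl], patch, out=img[sl])


def _paint_ball(img, center, radius, voxel, value):
    _paint_ellipsoid(img, center, (radius,) * 3, np.eye(3), voxel,
                     shell=value, interior=value, q_in=0.5, q_out=1.0)


def _paint_tube(img, p0, p1, radius, voxel, value):
    """Draw a cylindrical tube between two points (zyx μm)."""
    voxel = np.asarray(voxel, dtype=float)
    pad = radius + voxel.max()
    lo = np.maximum(np.floor((np.minimum(p0, p1) - pad) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + pad) / voxel).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[k], hi[k]) * voxel[k] for k in range(3)), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    v = p1 - p0
    L2 = float(v @ v)
    tproj = np.clip(((pts - p0) @ v) / L2, 0.0, 1.0) if L2 > 0 else 0.0
    closest = p0 + tproj[..., None] * v
    dist = np.linalg.norm(pts - closest, axis=-1)
    sl = tuple(slice(lo[k], hi[k]) for k in range(3))
    np.maximum(img[sl], np.where(dist <= radius, value, 0.0), out=img[sl])


def render_channel(truth: GroundTruth, t: int, channel: str,
                   config: Optional[SceneConfig] = None) -> np.ndarray:
    """Render one channel of one frame, noise-free, as float32 (z, y, x)."""
    cfg = config or truth.config
    if t >= cfg.n_frames:
        raise IndexError(f"frame {t} out of range ({cfg.n_frames} frames)")
    img = np.zeros(cfg.grid_shape, dtype=np.float32)
    vox = cfg.voxel_size
    if channel == "epithelial":
        for c in truth.cells:
            if c.kind == "epithelial":
                _paint_ellipsoid(img, c.centroids[t], c.axes[t], c.orient[t], vox,
                                 shell=1.0, interior=0.2)
    elif channel == "mesenchymal":
        # cells wrap around the ring circle: painted as overlapping arcs
        for ring in truth.rings:
            R = _rotation_to(ring.normal)
            e1, e2 = R[:, 1], R[:, 2]
            radius = ring.diameter[t] / 2.0
            m = len(ring.members)
            half_arc = (math.pi / m) * 1.08  # slight overlap keeps the loop closed
            for j in range(m):
                theta0 = ring.member_phases[j, t]
                n_seg = max(int(np.ceil(half_arc * 2 / 0.25)), 2)
                angles = theta0 + np.linspace(-half_arc, half_arc, n_seg + 1)
                pts = (
                    ring.center[None, :]
                    + radius * (np.cos(angles)[:, None] * e1[None, :]
                                + np.sin(angles)[:, None] * e2[None, :])
                )
                for p0, p1 in zip(pts[:-1], pts[1:]):
                    _paint_tube(img, p0, p1, ring.width, vox, 1.0)
    elif channel == "nuclei":
        for c in truth.cells:
            _paint_ball(img, c.centroids[t], cfg.nucleus_radius, vox, 1.0)
    elif channel == "endothelial":
        for i, j in truth.network_edges:
            _paint_tube(img, truth.network_nodes[i], truth.network_nodes[j],
                        cfg.vessel_radius, vox, 1.0)
    else:
        raise KeyError(f"unknown channel {channel!r}; expected one of {DEFAULT_CHANNELS}")
    return img


def _apply_noise(frame: np.ndarray, cfg: SceneConfig, t: int) -> np.ndarray:
    gauss_sd, poisson_scale = cfg.noise
    if gauss_sd == 0 and poisson_scale == 0:
        return frame
    rng = np.random.default_rng([cfg.seed, 1000 + t])
    out = frame.astype(np.float32)
    if poisson_scale > 0:
        out = rng.poisson(out * poisson_scale).astype(np.float32) / poisson_scale
    if gauss_sd > 0:
        out = out + rng.normal(0.0, gauss_sd, out.shape).astype(np.float32)
    return np.clip(out, 0.0, None)


def render_frame(truth: GroundTruth, t: int,
                 config: Optional[SceneConfig] = None) -> np.ndarray:
    """Render all four channels of frame ``t`` as float32 (c, z, y, x),
    applying the configured Poisson + Gaussian noise (noise-free when both
    parameters are 0).  Deterministic per (seed, frame)."""
    cfg = config or truth.config
    chans = [render_channel(truth, t, name, cfg) for name in DEFAULT_CHANNELS]
    return _apply_noise(np.stack(chans), cfg, t)


def render_movie(truth: GroundTruth, config: Optional[SceneConfig] = None) -> Volume4D:
    """Render the whole movie as a calibrated :class:`Volume4D`."""
    cfg = config or truth.config
    data = np.stack([render_frame(truth, t, cfg) for t in range(cfg.n_frames)])
    return Volume4D(data, cfg.voxel_size, cfg.frame_interval, DEFAULT_CHANNELS)


def render_labels(truth: GroundTruth, t: int, kind: str = "epithelial",
                  config: Optional[SceneConfig] = None) -> np.ndarray:
    """Ground-truth label volume at frame ``t``: each voxel carries the id
    (+1) of the nearest cell of ``kind`` whose ellipsoid contains it."""
    cfg = config or truth.config
    labels = np.zeros(cfg.grid_shape, dtype=np.int32)
    best_q = np.full(cfg.grid_shape, np.inf, dtype=np.float32)
    vox = np.asarray(cfg.voxel_size)
    if kind == "mesenchymal":
        # ring cells are arcs: label tube voxels by the nearest member phase
        for ring in truth.rings:
            R = _rotation_to(ring.normal)
            e1, e2 = R[:, 1], R[:, 2]
            radius = ring.diameter[t] / 2.0
            w = ring.width
            rmax = radius + w + float(vox.max())
            lo = np.maximum(np.floor((ring.center - rmax) / vox).astype(int), 0)
            hi = np.minimum(np.ceil((ring.center + rmax) / vox).astype(int) + 1, labels.shape)
            if np.any(lo >= hi):
                continue
            zz, yy, xx = np.meshgrid(
                *(np.arange(lo[k], hi[k]) * vox[k] - ring.center[k] for k in range(3)),
                indexing="ij",
            )
            d = np.stack([zz, yy, xx], axis=-1)
            u, v = d @ e1, d @ e2
            h = d @ ring.normal
            rho = np.sqrt(u * u + v * v)
            dist = np.sqrt((rho - radius) ** 2 + h * h)
            inside = dist <= w
            ang = np.arctan2(v, u)
            phases = ring.member_phases[:, t]
            # angular distance to each member phase
            diffs = np.abs(
                (ang[..., None] - phases[None, None, None, :] + np.pi) % (2 * np.pi) - np.pi
            )
            member = np.argmin(diffs, axis=-1)
            sl = tuple(slice(lo[k], hi[k]) for k in range(3))
            ids = np.asarray(ring.members, dtype=np.int32) + 1
            patch = labels[sl]
            patch[inside] = ids[member[inside]]
            labels[sl] = patch
        return labels
    for c in truth.cells:
        if c.kind != kind:
            continue
        center, axes, orient = c.centroids[t], c.axes[t], c.orient[t]
        rmax = float(np.max(axes)) + float(vox.max())
        lo = np.maximum(np.floor((center - rmax) / vox).astype(int), 0)
        hi = np.minimum(np.ceil((center + rmax) / vox).astype(int) + 1, labels.shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo[k], hi[k]) * vox[k] - center[k] for k in range(3)),
            indexing="ij",
        )
        d = np.stack([zz, yy, xx], axis=-1) @ orient
        q = np.sqrt(np.sum((d / axes) ** 2, axis=-1)).astype(np.float32)
        sl = tuple(slice(lo[k], hi[k]) for k in range(3))
        inside = (q <= 1.0) & (q < best_q[sl])
        labels[sl][inside] = c.cell_id + 1
        best_q[sl][inside] = q[inside]
    return labels


# ----------------------------------------------------------------------
# acquisition degradation
# ----------------------------------------------------------------------

def degrade_acquisition(movie: Volume4D, config: SceneConfig):
    """Apply the raw-acquisition artifacts that preprocessing must remove.

    A shear by ``skew_angle`` along the scan (z) axis displaces each z plane
    in x, exactly as an oblique-plane scan does; then a seeded random-walk
    translation is applied per frame.  Returns ``(raw, geometry, trace)``
    where geometry and trace hold the exact applied parameters, so de-skew
    and drift correction can be validated by round trip.
    """
    from .preprocess import DriftTrace, SkewGeometry  # local import, no cycle

    theta = config.skew_angle
    if abs(theta) >= 90:
        raise ValueError("|skew_angle| must be < 90 degrees")
    dz, dy, dx = movie.voxel_size
    shear_vox = math.tan(math.radians(theta)) * dz / dx
    T, C, nz, ny, nx = movie.data.shape

    if shear_vox != 0.0:
        extra = int(math.ceil(abs(shear_vox) * (nz - 1)))
        x0 = max(0.0, -shear_vox * (nz - 1))
        nxr = nx + extra
        matrix = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [-shear_vox, 0.0, 1.0]])
        offset = np.array([0.0, 0.0, -x0])
        sheared = np.zeros((T, C, nz, ny, nxr), dtype=movie.data.dtype)
        for ti in range(T):
            for ci in range(C):
                sheared[ti, ci] = ndi.affine_transform(
                    movie.data[ti, ci], matrix, offset=offset,
                    output_shape=(nz, ny, nxr), order=1, cval=0.0,
                )
    else:
        sheared = movie.data.copy()

    rng = np.random.default_rng([config.seed, 424242])
    steps = rng.normal(0.0, config.drift_sd, size=(T, 3)) if config.drift_sd > 0 else np.zeros((T, 3))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)

    if config.drift_sd > 0:
        raw = np.empty_like(sheared)
        for ti in range(T):
            for ci in range(C):
                raw[ti, ci] = ndi.shift(sheared[ti, ci], walk[ti], order=1, cval=0.0)
    else:
        raw = sheared

    geom = SkewGeometry(skew_angle=theta, scan_axis="z", scan_step=dz)
    trace = DriftTrace(shifts=walk)
    return movie.with_data(raw), geom, trace


# ----------------------------------------------------------------------
# alveolar boundary point clouds
# ----------------------------------------------------------------------

def alveolus_cloud(
    mode: str = "control",
    r0: float = 10.0,
    r1: float = 20.0,
    n_frames: int = 10,
    frame_interval: float = 1.0,
    center=(40.0, 40.0, 40.0),
    n_ring: int = 200,
    n_shell: int = 150,
    z_band: float = 0.4,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Boundary point cloud (t, x, y, z) of one expanding alveolar lumen.

    The inner alveolar boundary is emulated as a sphere whose equatorial
    belt is densely sampled (so a fixed-z planar slice yields a closed loop)
    plus a sparse shell elsewhere.  Under ``control`` the radius grows
    linearly r0 -> r1 over the movie; under ``wnt_activated`` /
    ``wnt_inhibited`` the radius stays at r0 (no expansion), mirroring the
    stalled perimeter growth of Wnt-perturbed slices.
    """
    rng = np.random.default_rng(seed)
    cx, cy, cz = center
    rows = []
    for t in range(n_frames):
        u = t / max(n_frames - 1, 1)
        r = r0 + (r1 - r0) * u if mode == "control" else r0
        tt = t * frame_interval
        # boundary points are roughly evenly spaced along the perimeter, as
        # extraction from pixel data yields; jittered grid rather than i.i.d.
        ang = (np.arange(n_ring) + rng.uniform(0.0, 1.0, n_ring)) * (2 * math.pi / n_ring)
        rr = r + rng.normal(0.0, noise_sd, n_ring)
        zb = rng.uniform(-z_band, z_band, n_ring)
        for a, radius, dzb in zip(ang, rr, zb):
            rows.append((tt, cx + radius * math.cos(a), cy + radius * math.sin(a), cz + dzb))
        # sparse points over the rest of the shell
        phi = np.arccos(rng.uniform(-1.0, 1.0, n_shell))
        th = rng.uniform(0.0, 2 * math.pi, n_shell)
        rs = r + rng.normal(0.0, noise_sd, n_shell)
        for p, q, radius in zip(phi, th, rs):
            z = cz + radius * math.cos(p)
            if abs(z - cz) < 2 * z_band:
                continue  # keep the equatorial band clean
            rows.append(
                (tt, cx + radius * math.sin(p) * math.cos(q),
                 cy + radius * math.sin(p) * math.sin(q), z)
            )
    return pd.DataFrame(rows, columns=["t", "x", "y", "z"])
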