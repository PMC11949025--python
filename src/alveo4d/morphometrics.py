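"""Cell-shape quantification: sphericity, flattening events, event scoring.

During alveologenesis, cuboidal AT2-like epithelial cells differentiate into
extremely thin AT1 cells.  The shape change is tracked with Wadell sphericity

    Psi = pi^(1/3) (6V)^(2/3) / A,

which is 1 for a perfect sphere and decreases toward 0 as a cell flattens.
This module turns per-cell sphericity time courses into discrete flattening
events (onset, duration, completion), population flattening fractions, and
scored alveologenesis events (clusters of cells that flatten while undergoing
a large concurrent outward soma displacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "sphericity",
    "spheroid_surface_area",
    "ellipsoid_surface_area",
    "ellipsoid_sphericity",
    "ShapeSeries",
    "FlatteningEvent",
    "detect_flattening",
    "flattening_fraction",
    "score_events",
]


def sphericity(volume: float, area: float) -> float:
    """Wadell sphericity ``pi^(1/3) (6V)^(2/3) / A``.

    Parameters are the enclosed volume (μm³) and surface area (μm²) of a
    closed shape; both must be strictly positive.  The measure is invariant
    to isotropic scaling.
    """
    if volume <= 0 or area <= 0:
        raise ValueError(f"sphericity requires V > 0 and A > 0; got V={volume}, A={area}")
    return math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area


def spheroid_surface_area(a: float, c: float) -> float:
    """Exact surface area of a spheroid with equatorial semi-axis ``a`` (×2)
    and polar semi-axis ``c`` (oblate for c < a, prolate for c > a)."""
    if a <= 0 or c <= 0:
        raise ValueError("semi-axes must be positive")
    if abs(a - c) < 1e-12 * max(a, c):
        return 4.0 * math.pi * a * a
    if c < a:  # oblate
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * a * a + math.pi * (c * c / e) * math.log((1 + e) / (1 - e))
    # prolate
    e = math.sqrt(1.0 - (a / c) ** 2)
    return 2.0 * math.pi * a * a * (1.0 + (c / (a * e)) * math.asin(e))


def ellipsoid_surface_area(axes: Sequence[float]) -> float:
    """Surface area of a general triaxial ellipsoid (Legendre form).

    Spheroids (two equal axes) use the closed elementary form; the triaxial
    case evaluates the incomplete elliptic integrals.
    """
    a, b, c = sorted((float(x) for x in axes), reverse=True)
    if a <= 0:
        raise ValueError("semi-axes must be positive")
    rel = 1e-9 * a
    if abs(a - b) < rel:
        return spheroid_surface_area(a, c)
    if abs(b - c) < rel:
        return spheroid_surface_area(b, a)
    from scipy.special import ellipeinc, ellipkinc

    phi = math.acos(c / a)
    k2 = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    F = ellipkinc(phi, k2)
    E = ellipeinc(phi, k2)
    s = math.sin(phi)
    return 2 * math.pi * c * c + (2 * math.pi * a * b / s) * (
        E * s * s + F * math.cos(phi) ** 2
    )


def ellipsoid_sphericity(axes: Sequence[float]) -> float:
    """Analytic Wadell sphericity of an ellipsoid with the given semi-axes."""
    a, b, c = (float(x) for x in axes)
    volume = 4.0 / 3.0 * math.pi * a * b * c
    return sphericity(volume, ellipsoid_surface_area((a, b, c)))


@dataclass
class ShapeSeries:
    """Per-cell shape time course: sphericity (and optionally V, A, centroid)
    on the frames where the cell is present."""

    cell_id: int
    times: np.ndarray  # hours
    psi: np.ndarray
    volume: Optional[np.ndarray] = None
    area: Optional[np.ndarray] = None
    centroids: Optional[np.ndarray] = None  # (n, 3) μm, (z, y, x)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.times.shape != self.psi.shape:
            raise ValueError("times and psi must have equal length")


@dataclass
class FlatteningEvent:
    """A detected round-to-flat transition of one cell."""

    cell_id: int
    onset_frame: int
    onset_time: float  # hours
    duration: float  # hours, full-transition estimate
    completed: bool
    displacement: float = float("nan")  # μm soma displacement over the event
    psi_start: float = float("nan")
    psi_end: float = float("nan")


def _crossing_time(times: np.ndarray, values: np.ndarray, level: float, start: int) -> float:
    """Sub-frame time at which a declining series first crosses below ``level``."""
    below = values[start:] < level
    if not below.any():
        return float(times[-1])
    i = start + int(np.argmax(below))
    if i == 0:
        return float(times[0])
    v0, v1 = values[i - 1], values[i]
    if v0 == v1:
        return float(times[i])
    frac = (v0 - level) / (v0 - v1)
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def detect_flattening(
    series: ShapeSeries,
    hi: float = 0.85,
    lo: float = 0.6,
    min_drop_frames: int = 3,
    smooth_window: int = 3,
) -> Optional[FlatteningEvent]:
    """Detect a round-to-flat transition in a sphericity time course.

    The trace is median-smoothed, then an event is reported when the series
    crosses below ``hi`` and subsequently below ``lo`` in a sustained decline.
    Cells that are already flat at the start (first smoothed value below
    ``hi``) report no event; rising-sphericity events are never reported.

    The returned duration is the full-transition time: the drop between the
    pre- and post-transition plateau levels divided by the fitted decline
    slope.  The ``hi``/``lo`` crossings alone span only the thresholded part
    of the transition; dividing the plateau-to-plateau drop by the decline
    slope extrapolates to the complete round-to-flat period, which is exact
    for a linear decline and robust to the threshold choice.
    """
    psi = np.asarray(series.psi, dtype=float)
    times = np.asarray(series.times, dtype=float)
    n = psi.size
    if n < max(min_drop_frames, 3):
        return None
    sm = ndi.median_filter(psi, size=smooth_window, mode="nearest")

    below_hi = sm < hi
    if not below_hi.any():
        return None  # never leaves the round plateau
    i_hi = int(np.argmax(below_hi))
    if i_hi == 0:
        return None  # flat (or declining) from the very start: pre-flattened
    psi_start = float(np.median(sm[:i_hi]))
    if psi_start < hi:
        return None

    below_lo = sm[i_hi:] <= lo
    completed = bool(below_lo.any())
    i_lo = i_hi + int(np.argmax(below_lo)) if completed else n - 1

    tail_len = max(3, n // 10)
    psi_end = float(np.median(sm[-tail_len:])) if completed else float(sm[i_hi:].min())
    drop = psi_start - psi_end
    if drop < (hi - lo):
        return None  # decline too shallow to count as flattening

    # decline segment: frames strictly between the two plateaus
    band_lo = psi_end + 0.1 * drop
    band_hi = psi_start - 0.1 * drop
    in_band = (sm <= band_hi) & (sm >= band_lo)
    # longest contiguous in-band run that contains (or abuts) the hi crossing
    runs = []
    start = None
    for i, flag in enumerate(in_band):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, n))
    seg = None
    for s0, s1 in runs:
        if s0 <= i_hi < s1 or (seg is None and s0 >= i_hi):
            seg = (s0, s1)
            if s0 <= i_hi < s1:
                break
    if seg is None or seg[1] - seg[0] < min_drop_frames:
        return None

    s0, s1 = seg
    slope, intercept = np.polyfit(times[s0:s1], sm[s0:s1], 1)
    if slope >= 0:
        return None
    duration = drop / (-slope)
    onset_time = (psi_start - intercept) / slope
    onset_time = float(np.clip(onset_time, times[0], times[-1]))
    onset_frame = int(np.searchsorted(times, onset_time))
    onset_frame = min(max(onset_frame, 0), n - 1)

    displacement = float("nan")
    if series.centroids is not None:
        end_time = min(onset_time + duration, times[-1])
        end_frame = min(int(np.searchsorted(times, end_time)), n - 1)
        displacement = float(
            np.linalg.norm(series.centroids[end_frame] - series.centroids[onset_frame])
        )
    return FlatteningEvent(
        cell_id=series.cell_id,
        onset_frame=onset_frame,
        onset_time=onset_time,
        duration=float(duration),
        completed=completed,
        displacement=displacement,
        psi_start=psi_start,
        psi_end=psi_end,
    )


def flattening_fraction(events: Iterable[Optional[FlatteningEvent]], population: int) -> float:
    """Percentage of a cell population with a completed flattening event."""
    if population <= 0:
        raise ValueError("population must be positive")
    n_completed = sum(1 for e in events if e is not None and e.completed)
    return 100.0 * n_completed / population


@dataclass
class AlveologenesisEvent:
    """A scored alveologenesis event: a cluster of epithelial cells that
    flatten while undergoing concurrent large outward soma displacement."""

    cell_ids: tuple
    onset_time: float  # hours, earliest member onset
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))


def score_events(
    tracks,
    shape_series: Sequence[ShapeSeries],
    min_cluster: int = 2,
    min_displacement: float = 60.0,
    cluster_radius: float = 25.0,
    window_h: float = 24.0,
    hi: float = 0.85,
    lo: float = 0.6,
):
    """Score alveologenesis events from aligned tracks and shape series.

    A computational surrogate for manual blinded event scoring: an event is a
    cluster of at least ``min_cluster`` cells whose somata start within
    ``cluster_radius`` μm of each other, whose flattening onsets fall within
    ``window_h`` hours of each other, and which each undergo a net soma
    displacement of at least ``min_displacement`` μm (default 60 μm, the lower
    bound of the extrusion distance through a mesenchymal ring) concurrent
    with a sphericity decline.

    Returns ``(events, rate)`` where ``rate`` is events per hour of movie.
    """
    track_by_id = {t.track_id: t for t in tracks}
    candidates = []
    t_min, t_max = np.inf, -np.inf
    for tr in tracks:
        tt = np.asarray(tr.times if tr.times is not None else tr.frames, dtype=float)
        if tt.size:
            t_min = min(t_min, tt[0])
            t_max = max(t_max, tt[-1])
    for s in shape_series:
        ev = detect_flattening(s, hi=hi, lo=lo)
        if ev is None or not ev.completed:
            continue
        tr = track_by_id.get(s.cell_id)
        if tr is None:
            continue
        pts = np.asarray(tr.points, dtype=float)
        times = np.asarray(tr.times, dtype=float)
        i0 = min(int(np.searchsorted(times, ev.onset_time)), len(times) - 1)
        i1 = min(int(np.searchsorted(times, ev.onset_time + ev.duration)), len(times) - 1)
        disp = float(np.linalg.norm(pts[i1] - pts[i0]))
        if disp < min_displacement:
            continue
        candidates.append((s.cell_id, ev.onset_time, pts[i0]))

    # single-linkage clustering on start position and onset-time proximity
    m = len(candidates)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            if (
                np.linalg.norm(candidates[i][2] - candidates[j][2]) <= cluster_radius
                and abs(candidates[i][1] - candidates[j][1]) <= window_h
            ):
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(m):
        clusters.setdefault(find(i), []).append(i)
    events = []
    for members in clusters.values():
        if len(members) >= min_cluster:
            ids = tuple(sorted(candidates[i][0] for i in members))
            onset = min(candidates[i][1] for i in members)
            centroid = np.mean([candidates[i][2] for i in members], axis=0)
            events.append(AlveologenesisEvent(ids, onset, centroid))
    duration_h = (t_max - t_min) if np.isfinite(t_max - t_min) and t_max > t_min else np.nan
    rate = len(events) / duration_h if duration_h and np.isfinite(duration_h) else float("nan")
    return events, rate
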