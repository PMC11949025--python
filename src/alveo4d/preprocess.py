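"""Raw-acquisition preprocessing: de-skew and drift correction.

Oblique-plane light-sheet stacks are sheared along the scan axis: each z
plane is displaced in x in proportion to its scan position.  :func:`deskew`
undoes this with an inverse affine resampling.  Slow stage/sample drift over
multi-day time lapses is measured by phase cross-correlation between
consecutive frames (:func:`estimate_drift`), accumulated into a per-frame
trace, and removed by translating each frame (:func:`correct_drift`).

All resampling is linear (order 1): nearest-neighbour aliases thin membrane
shells and higher orders ring at sharp edges.  Out-of-field voxels are
filled with 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .io import Volume4D

__all__ = [
    "SkewGeometry",
    "DriftTrace",
    "deskew",
    "estimate_drift",
    "estimate_drift_trace",
    "correct_drift",
]


@dataclass
class SkewGeometry:
    """Acquisition shear geometry: angle between the light-sheet plane normal
    and the stage scan direction, the scan axis, and the scan step in μm."""

    skew_angle: float  # degrees
    scan_axis: str = "z"
    scan_step: float = 1.0  # μm

    def __post_init__(self) -> None:
        if not math.isfinite(self.skew_angle):
            raise ValueError("skew_angle must be finite")
        if abs(self.skew_angle) >= 90:
            raise ValueError("|skew_angle| must be < 90 degrees")


@dataclass
class DriftTrace:
    """Cumulative per-frame translation (dz, dy, dx) in voxels; frame 0 is
    the reference and must be (0, 0, 0)."""

    shifts: np.ndarray  # (T, 3)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 3:
            raise ValueError("drift trace must be (T, 3)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("drift trace must be finite")
        if np.any(self.shifts[0] != 0):
            raise ValueError("drift trace must start at (0, 0, 0)")

    def __len__(self) -> int:
        return len(self.shifts)

    def to_csv(self, path) -> Path:
        df = pd.DataFrame(self.shifts, columns=["dz", "dy", "dx"])
        df.insert(0, "frame", np.arange(len(df)))
        path = Path(path)
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "DriftTrace":
        df = pd.read_csv(path, comment="#")
        return cls(df[["dz", "dy", "dx"]].to_numpy())


def deskew(raw: Volume4D, geom: SkewGeometry) -> Volume4D:
    """Undo the acquisition shear with the inverse affine resampling.

    The shear displaces plane z by ``tan(angle) * z * dz / dx`` voxels in x;
    the inverse shifts each plane back.  An angle of 0 is the identity.  The
    x extent is preserved (the sheared input is already padded); newly
    exposed voxels are 0.
    """
    theta = geom.skew_angle
    if theta == 0.0:
        return raw.with_data(raw.data.copy())
    dz, dy, dx = raw.voxel_size
    step = geom.scan_step if geom.scan_step else dz
    shear_vox = math.tan(math.radians(theta)) * step / dx
    T, C, nz, ny, nx = raw.data.shape
    x0 = max(0.0, -shear_vox * (nz - 1))
    # inverse of out_x = in_x + shear*z + x0  =>  in_x = out_x' + shear*z + x0
    matrix = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [shear_vox, 0.0, 1.0]])
    offset = np.array([0.0, 0.0, x0])
    out = np.zeros_like(raw.data)
    for t in range(T):
        for c in range(C):
            out[t, c] = ndi.affine_transform(
                raw.data[t, c], matrix, offset=offset,
                output_shape=(nz, ny, nx), order=1, cval=0.0,
            )
    return raw.with_data(out)


def estimate_drift(ref_frame: np.ndarray, moving_frame: np.ndarray,
                   upsample: int = 1) -> np.ndarray:
    """Translation (dz, dy, dx, voxels) to apply to ``moving_frame`` to align
    it to ``ref_frame``, from the peak of the normalised cross-power
    spectrum, with 1/upsample sub-voxel precision."""
    ref = np.asarray(ref_frame)
    mov = np.asarray(moving_frame)
    if ref.shape != mov.shape:
        raise ValueError("frames must share a shape")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if not np.any(ref) or not np.any(mov):
        raise ValueError("phase correlation is undefined for an all-zero frame")
    shift, _error, _phase = phase_cross_correlation(
        ref, mov, upsample_factor=upsample, normalization=None
    )
    return np.asarray(shift, dtype=float)


def estimate_drift_trace(movie: Volume4D, channel: str = "mesenchymal",
                         upsample: int = 10) -> DriftTrace:
    """Accumulated pairwise frame-to-frame drift of one channel.

    Pairwise estimates (frame t-1 vs t) are summed rather than registering
    everything to frame 0, which stays robust as tissue content slowly
    changes over multi-day movies.  The trace holds the *displacement* of
    each frame relative to frame 0 (the negated alignment shift), matching
    the convention of :func:`correct_drift`.
    """
    stack = movie.channel(channel)
    T = stack.shape[0]
    shifts = np.zeros((T, 3))
    for t in range(1, T):
        shifts[t] = shifts[t - 1] - estimate_drift(stack[t - 1], stack[t], upsample)
    return DriftTrace(shifts=shifts)


def correct_drift(movie: Volume4D, trace: DriftTrace, subpixel: bool = True) -> Volume4D:
    """Translate each frame by the negated drift to re-align the movie.

    ``trace`` holds each frame's displacement relative to frame 0; frames are
    shifted by its negation (linear interpolation by default, or rounded to
    integer voxels when ``subpixel`` is False).
    """
    if len(trace) != movie.n_frames:
        raise ValueError(
            f"drift trace length {len(trace)} != movie frames {movie.n_frames}"
        )
    out = np.empty_like(movie.data)
    for t in range(movie.n_frames):
        shift = -trace.shifts[t]
        if not subpixel:
            shift = np.round(shift)
        if np.all(shift == 0):
            out[t] = movie.data[t]
            continue
        for c in range(movie.n_channels):
            out[t, c] = ndi.shift(movie.data[t, c], shift, order=1, cval=0.0)
    return movie.with_data(out)
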