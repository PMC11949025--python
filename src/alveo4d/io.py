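"""Volume containers and calibrated I/O.

Movies are held in memory as 5-D arrays indexed ``(t, c, z, y, x)`` together
with their physical calibration: voxel size ``(dz, dy, dx)`` in micrometres and
the time-lapse frame interval in hours.  On disk two containers are supported:

* multipage TIFF (one page per (t, c, z) plane) with the calibration embedded
  in the shaped-metadata description, and
* a chunked zarr group holding the full-resolution level under ``"0"`` with
  calibration in the group attributes.

Both round-trip array values bit-exactly and calibration to full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "Volume4D",
    "CalibrationError",
    "read_volume",
    "write_volume",
]

DEFAULT_CHANNELS = ("epithelial", "mesenchymal", "nuclei", "endothelial")


class CalibrationError(ValueError):
    """A stored volume is missing a required physical-calibration field."""


@dataclass
class Volume4D:
    """A calibrated 4-D (time, channel) fluorescence volume.

    Parameters
    ----------
    data:
        Intensity array of shape ``(t, c, z, y, x)``.
    voxel_size:
        ``(dz, dy, dx)`` in micrometres, all strictly positive.
    frame_interval:
        Time between frames in hours.
    channel_names:
        One unique name per channel.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval: float
    channel_names: tuple[str, ...] = field(default=DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"Volume4D data must be rank 5 (t, c, z, y, x); got rank {self.data.ndim}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 strictly positive values; got {self.voxel_size}")
        self.frame_interval = float(self.frame_interval)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.channel_names = tuple(str(c) for c in self.channel_names)[: self.data.shape[1]]
        if len(self.channel_names) != self.data.shape[1]:
            # pad with generic names if fewer names than channels were given
            extra = tuple(
                f"ch{i}" for i in range(len(self.channel_names), self.data.shape[1])
            )
            self.channel_names = self.channel_names + extra
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names must be unique; got {self.channel_names}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(t, z, y, x)`` stack for one named channel."""
        return self.data[:, self.channel_index(name)]

    def with_data(self, data: np.ndarray, voxel_size=None) -> "Volume4D":
        return Volume4D(
            data,
            voxel_size if voxel_size is not None else self.voxel_size,
            self.frame_interval,
            self.channel_names,
        )


def _metadata(vol: Volume4D) -> dict:
    return {
        "axes": "TCZYX",
        "voxel_size": list(vol.voxel_size),
        "frame_interval": vol.frame_interval,
        "channel_names": list(vol.channel_names),
    }


def write_volume(vol: Volume4D, path: str | Path) -> Path:
    """Write a :class:`Volume4D` to ``path`` (``.tif``/``.tiff`` or ``.zarr``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.data, metadata=_metadata(vol))
    elif suffix == ".zarr":
        import zarr

        group = zarr.open_group(str(path), mode="w")
        arr = group.create_array(
            "0", shape=vol.data.shape, dtype=vol.data.dtype, overwrite=True
        )
        arr[:] = vol.data
        group.attrs.update(_metadata(vol))
        group.attrs["multiscales"] = [{"datasets": [{"path": "0"}], "axes": "tczyx"}]
    else:
        raise ValueError(
            f"unknown volume format {suffix!r}; supported formats: .tif, .tiff, .zarr"
        )
    return path


def _check_calibration(meta: dict, path: Path) -> tuple:
    for key in ("voxel_size", "frame_interval"):
        if key not in meta or meta[key] is None:
            raise CalibrationError(
                f"{path} is missing calibration field {key!r}"
            )
    channels = meta.get("channel_names")
    return (
        tuple(float(v) for v in meta["voxel_size"]),
        float(meta["frame_interval"]),
        tuple(channels) if channels else None,
    )


def read_volume(path: str | Path) -> Volume4D:
    """Read a volume written by :func:`write_volume`.

    Raises :class:`CalibrationError` naming the missing field when a store has
    no physical calibration, and :class:`ValueError` for unknown formats.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    elif suffix == ".zarr":
        import zarr

        group = zarr.open_group(str(path), mode="r")
        data = np.asarray(group["0"][:])
        meta = dict(group.attrs)
    else:
        raise ValueError(
            f"unknown volume format {suffix!r}; supported formats: .tif, .tiff, .zarr"
        )
    voxel_size, frame_interval, channels = _check_calibration(meta, path)
    data = np.asarray(data)
    while data.ndim < 5:  # singleton t/c axes dropped by TIFF squeeze
        data = data[np.newaxis]
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return Volume4D(data, voxel_size, frame_interval, channels)


def write_table(df, path: str | Path, header_comment: str | None = None) -> Path:
    """Write a DataFrame as CSV, optionally with a ``#`` comment header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
    return path
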