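"""TIFF and table I/O helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .core import DEFAULT_VOXEL_SIZE, VolumeImage


def read_volume(path, voxel_size=DEFAULT_VOXEL_SIZE, channel: str = "") -> VolumeImage:
    """Read a (multi-page) TIFF stack as a 3D volume; 2D files gain a z-axis."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2D or 3D TIFF, got shape {data.shape}")
    return VolumeImage(data.astype(float), voxel_size, channel=channel or Path(path).stem)


def write_volume(path, volume: VolumeImage, dtype=np.float32) -> None:
    """Write a volume as a multi-page TIFF with the voxel size in metadata."""
    vz, vy, vx = volume.voxel_size
    tifffile.imwrite(
        str(path),
        np.asarray(volume.data, dtype=dtype),
        metadata={"axes": "ZYX", "spacing": vz, "unit": "um"},
        resolution=(1.0 / vx, 1.0 / vy),
    )


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.int32))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(str(path))
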