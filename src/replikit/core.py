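"""Core in-memory containers shared across the pipeline.

All 3D grids are indexed ``(z, y, x)`` and carry an anisotropic voxel size in
micrometers in the same axis order.  Physical quantities (distances, volumes,
spot sigmas) are always expressed in µm; voxel units appear only at the array
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default voxel size (z, y, x) in µm for high-resolution 3D acquisitions.
DEFAULT_VOXEL_SIZE: tuple[float, float, float] = (0.29, 0.125, 0.125)


@dataclass
class VolumeImage:
    """One channel of a 3D intensity grid with per-axis voxel size in µm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z,y,x) array, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel size must be three positive lengths, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.voxel_size))

    def to_um(self, zyx: np.ndarray) -> np.ndarray:
        """Convert voxel-index coordinates (possibly fractional) to µm."""
        return np.asarray(zyx, dtype=float) * np.asarray(self.voxel_size)

    def with_data(self, data: np.ndarray, channel: str | None = None) -> "VolumeImage":
        return VolumeImage(data, self.voxel_size, self.channel if channel is None else channel)


@dataclass
class NucleusMask:
    """Binary 3D nucleus mask aligned to its source volume.

    Invariant: non-empty and a single 26-connected component.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("nucleus mask must be 3D (z,y,x)")
        if not self.data.any():
            raise ValueError("nucleus mask is empty")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def volume_um3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume

    def n_components(self) -> int:
        from scipy import ndimage

        _, n = ndimage.label(self.data, structure=np.ones((3, 3, 3), dtype=bool))
        return int(n)


@dataclass
class SpotLabelMap:
    """Labeled 3D objects (foci / replicons / FISH spots) plus a per-object table.

    ``table`` columns: label, n_voxels, volume_um3, z_um, y_um, x_um
    (intensity-weighted centroid), sum_intensity, seed_z, seed_y, seed_x.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D (z,y,x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def binary(self) -> np.ndarray:
        return self.labels > 0

    def centroids_um(self) -> np.ndarray:
        """(n, 3) intensity-weighted centroids in µm, ordered by label."""
        if self.table.empty:
            return np.empty((0, 3))
        return self.table[["z_um", "y_um", "x_um"]].to_numpy()
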