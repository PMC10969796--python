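"""3D nucleus mask construction from the DAPI channel, and channel masking.

Pipeline: Gaussian blur (xy radius in px, z radius scaled by the voxel
anisotropy) → min–max normalization → global Otsu threshold → keep the
largest 26-connected component → ``dilations`` dilations → 3D hole filling →
``erosions`` erosions.  Because of the normalization, the mask is invariant
to affine rescaling of the input intensities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import NucleusMask, VolumeImage

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.zeros_like(a, dtype=float)
    return (a - lo) / (hi - lo)


def segment_nucleus_3d(
    dapi: VolumeImage,
    sigma_px: float = 2.0,
    dilations: int = 2,
    erosions: int = 2,
    threshold: float | None = None,
) -> NucleusMask:
    """Segment the nucleus from a 3D DAPI stack.

    ``sigma_px`` is the xy blur radius in pixels; the z radius is divided by
    the z/xy voxel-size ratio so the blur is isotropic in µm.  ``threshold``
    (on the normalized [0, 1] image) overrides Otsu.  If more than one object
    survives thresholding only the largest is kept (with a warning); an empty
    mask raises, reporting the threshold used.
    """
    vs = dapi.voxel_size
    anis = vs[0] / vs[1]
    smooth = ndimage.gaussian_filter(dapi.data.astype(float), sigma=(sigma_px / anis, sigma_px, sigma_px))
    norm = _minmax(smooth)
    thr = float(threshold_otsu(norm)) if threshold is None else float(threshold)
    fg = norm > thr
    if not fg.any():
        raise ValueError(f"nucleus threshold {thr:.4f} yields an empty mask")
    labels, n = ndimage.label(fg, structure=_STRUCT26)
    if n > 1:
        log.warning("nucleus segmentation found %d objects; keeping the largest", n)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    if dilations:
        fg = ndimage.binary_dilation(fg, iterations=dilations)
    fg = ndimage.binary_fill_holes(fg)
    if erosions:
        fg = ndimage.binary_erosion(fg, iterations=erosions)
    if not fg.any():
        raise ValueError("morphological post-processing emptied the nucleus mask")
    labels, n = ndimage.label(fg, structure=_STRUCT26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    return NucleusMask(fg, vs)


def mask_channel(channel: VolumeImage, mask: NucleusMask) -> VolumeImage:
    """Zero a channel outside the nucleus (voxelwise min with the scaled mask)."""
    if channel.data.shape != mask.data.shape:
        raise ValueError(f"shape mismatch: channel {channel.data.shape} vs mask {mask.data.shape}")
    return channel.with_data(np.where(mask.data, channel.data, 0.0))


def quantize_8bit(volume: VolumeImage) -> VolumeImage:
    """Optional parity step mirroring a 16→8-bit conversion (min–max scaled)."""
    q = np.round(_minmax(volume.data.astype(float)) * 255).astype(np.uint8)
    return volume.with_data(q)


def mask_qc(mask: NucleusMask) -> pd.DataFrame:
    """One-row QC report: volume, extent, sphericity proxy.

    Sphericity is estimated as (π^{1/3} (6V)^{2/3}) / A with the surface area A
    approximated from face counts between mask and background voxels, scaled
    by the anisotropic face areas.
    """
    vs = mask.voxel_size
    vol = mask.volume_um3
    area = 0.0
    face = {0: vs[1] * vs[2], 1: vs[0] * vs[2], 2: vs[0] * vs[1]}
    m = mask.data
    for ax in range(3):
        d = np.diff(m.astype(np.int8), axis=ax)
        area += float(np.abs(d).sum()) * face[ax]
        # boundary faces at the volume edge
        first = np.take(m, 0, axis=ax)
        last = np.take(m, -1, axis=ax)
        area += (float(first.sum()) + float(last.sum())) * face[ax]
    sphericity = (np.pi ** (1 / 3) * (6 * vol) ** (2 / 3)) / area if area > 0 else np.nan
    return pd.DataFrame(
        [
            {
                "volume_um3": vol,
                "n_voxels": int(m.sum()),
                "surface_um2": area,
                "sphericity": sphericity,
                "n_components": mask.n_components(),
            }
        ]
    )
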