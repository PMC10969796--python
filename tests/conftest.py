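"""Shared fixtures: synthetic nuclei are expensive, so they are module-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from replikit.core import NucleusMask
from replikit.simulate import NucleusSimSpec, generate_nucleus_volume


@pytest.fixture(scope="session")
def nucleus50():
    """Default-conditions nucleus: 50 PCNA spots, separation >= 4 sigma, SNR 10."""
    spec = NucleusSimSpec(seed=1, n_spots={"pcna": 50})
    channels, truth = generate_nucleus_volume(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def nucleus50_mask(nucleus50):
    spec, _, truth = nucleus50
    return NucleusMask(truth.mask, spec.voxel_size)


@pytest.fixture(scope="session")
def small_noiseless_nucleus():
    """Small, fast, noise-free nucleus for exactness checks."""
    spec = NucleusSimSpec(
        shape=(16, 64, 64),
        semi_axes_um=(1.8, 3.0, 3.0),
        n_spots={"pcna": 10},
        noise_sd=0.0,
        poisson=False,
        seed=2,
    )
    channels, truth = generate_nucleus_volume(spec)
    return spec, channels, truth


def centroid_errors_vox(truth, spots, voxel_size) -> np.ndarray:
    """Per-planted-spot distance (voxel units) to the nearest recovered centroid."""
    from scipy.spatial import cKDTree

    tc = truth.spots[["z_um", "y_um", "x_um"]].to_numpy()
    cc = spots.centroids_um()
    _, idx = cKDTree(cc).query(tc)
    return np.linalg.norm((tc - cc[idx]) / np.asarray(voxel_size), axis=1)
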