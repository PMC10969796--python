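"""Synthetic 3D nucleus images, cell populations and origin sets with ground truth.

The generator plants everything the downstream analyses estimate, so every
operation in the pipeline can be benchmarked against exact truth:

* an ellipsoidal nucleus whose DAPI texture is a Potts-coupled 7-class
  compaction field with strictly increasing class mean intensities,
* per-channel diffraction-limited spots (3D Gaussians, isotropic in µm,
  sampled onto the anisotropic voxel grid) with controlled spatial placement
  (dispersed / peripheral / clustered) and minimum separation,
* a controllable colocalization fraction between two named channels
  (that fraction of probe spots shares centroids with target spots exactly),
* a controllable EdU:PCNA total-signal ratio (applied to the
  background-subtracted spot signal before noise),
* read noise (Gaussian) plus shot noise (Poisson) on the clean signal,
* 2D-screen cell populations with planted G1/S/G2 phases, and genomic
  origin interval sets with known gap structure.

All outputs are bit-identical for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_VOXEL_SIZE, VolumeImage


class SpotPlacementError(RuntimeError):
    """Raised when spots cannot be placed at the requested separation."""

    def __init__(self, n_failed: int, n_requested: int):
        self.n_failed = n_failed
        super().__init__(
            f"could not place {n_failed} of {n_requested} spots inside the nucleus "
            f"at the requested minimum separation; relax separation or reduce n_spots"
        )


@dataclass
class NucleusSimSpec:
    """Parameters of one synthetic multichannel nucleus volume.

    Lengths are µm; intensities are arbitrary units.  ``n_spots`` maps channel
    name to planted spot count.  ``coloc_pair``/``coloc_fraction`` force that
    fraction of the first channel's spots to share centroids with spots of the
    second channel.  ``edu_pcna_ratio`` rescales the EdU spot signal so that
    (background-subtracted) total EdU = ratio x total PCNA before noise.
    """

    shape: tuple[int, int, int] = (32, 128, 128)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    semi_axes_um: tuple[float, float, float] = (3.5, 6.0, 6.0)
    n_spots: Mapping[str, int] = field(default_factory=lambda: {"pcna": 50})
    spot_sigma_um: float = 0.25
    spot_amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 10.0
    poisson: bool = True
    placement: str = "dispersed"  # dispersed | peripheral | clustered
    min_separation_um: float | None = None  # default 4 sigma
    coloc_pair: tuple[str, str] | None = None
    coloc_fraction: float = 0.0
    edu_pcna_ratio: float | None = None
    n_classes: int = 7
    beta: float = 1.0
    class_mean_base: float = 100.0
    class_mean_step: float = 30.0
    n_clusters: int = 4  # used by the "clustered" placement mode
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.shape):
            raise ValueError("image shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")
        if self.spot_sigma_um <= 0:
            raise ValueError("spot sigma must be > 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("colocalization fraction must lie in [0, 1]")
        if self.edu_pcna_ratio is not None and self.edu_pcna_ratio <= 0:
            raise ValueError("edu_pcna_ratio must be > 0")
        if self.placement not in ("dispersed", "peripheral", "clustered"):
            raise ValueError(f"unknown placement mode {self.placement!r}")
        if self.beta < 0:
            raise ValueError("spatial coupling beta must be >= 0")
        if self.n_classes < 1:
            raise ValueError("need at least one compaction class")
        if any(n < 0 for n in self.n_spots.values()):
            raise ValueError("spot counts must be >= 0")

    @property
    def snr(self) -> float:
        """Peak spot amplitude over Gaussian read-noise sd."""
        return float("inf") if self.noise_sd == 0 else self.spot_amplitude / self.noise_sd

    @property
    def min_separation(self) -> float:
        """Default centroid separation: 4 sigma, or 6 sigma when a colocalization
        pair is planted (so a shared spot's mask, radius ~2 sigma, can never
        touch the mask of a non-partner spot and the planted count is exact)."""
        if self.min_separation_um is not None:
            return self.min_separation_um
        return (6.0 if self.coloc_pair is not None else 4.0) * self.spot_sigma_um


@dataclass
class GroundTruth:
    """Planted truth for one generator call.

    ``spots``: one row per planted spot (channel, centroid µm, sigma, amplitude,
    coloc flag).  ``compaction``: per-voxel class label (0 outside the nucleus).
    ``mask``: the true ellipsoid mask.  Population and origin generators fill
    ``cells`` / ``gaps`` instead.
    """

    spots: pd.DataFrame = field(default_factory=pd.DataFrame)
    compaction: np.ndarray | None = None
    mask: np.ndarray | None = None
    n_colocalizing: int = 0
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    gaps: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Potts-coupled compaction label field


def sample_potts_labels(
    mask: np.ndarray,
    n_classes: int,
    beta: float,
    rng: np.random.Generator,
    sweeps: int = 50,
) -> np.ndarray:
    """Sample a Potts label field on the masked voxels by checkerboard Gibbs sweeps.

    6-neighborhood, uniform external field.  ``beta`` is the coupling strength;
    beta=0 gives i.i.d. uniform labels.  Returns labels in 1..K inside the mask
    and 0 outside.  50 sweeps give an approximate but well-mixed sample, which
    is all the recovery benchmarks need.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[mask] = rng.integers(1, n_classes + 1, size=int(mask.sum()))
    if beta == 0.0 or n_classes == 1:
        return labels

    zz, yy, xx = np.indices(mask.shape)
    parity = (zz + yy + xx) % 2
    for _ in range(sweeps):
        for color in (0, 1):
            counts = _neighbor_class_counts(labels, mask, n_classes)
            upd = mask & (parity == color)
            # Gibbs: P(k) ∝ exp(beta * #neighbors in class k)
            logits = beta * counts[:, upd]
            logits -= logits.max(axis=0)
            p = np.exp(logits)
            p /= p.sum(axis=0)
            u = rng.random(p.shape[1])
            labels[upd] = (p.cumsum(axis=0) < u).sum(axis=0) + 1
    return labels


def _neighbor_class_counts(labels: np.ndarray, mask: np.ndarray, n_classes: int) -> np.ndarray:
    """(K, n_voxels...) count of 6-neighbors in each class; out-of-mask neighbors ignored."""
    counts = np.zeros((n_classes,) + labels.shape, dtype=np.int8)
    for axis in range(3):
        for shift in (1, -1):
            shifted = np.roll(labels, shift, axis=axis)
            # rolled-in border voxels are not real neighbors
            edge = [slice(None)] * 3
            edge[axis] = 0 if shift == 1 else -1
            shifted[tuple(edge)] = 0
            for k in range(1, n_classes + 1):
                counts[k - 1] += shifted == k
    return counts


# ---------------------------------------------------------------------------
# Spot placement and rendering


def _ellipsoid_mask(shape, voxel_size, semi_axes_um) -> np.ndarray:
    center = (np.array(shape) - 1) / 2.0 * np.array(voxel_size)
    grids = np.indices(shape).astype(float)
    d2 = np.zeros(shape)
    for ax in range(3):
        d2 += ((grids[ax] * voxel_size[ax] - center[ax]) / semi_axes_um[ax]) ** 2
    return d2 <= 1.0


def _place_points(
    spec: NucleusSimSpec,
    n: int,
    rng: np.random.Generator,
    other: list[np.ndarray] | None = None,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample n centroids (µm) inside the nucleus honoring separation.

    Within a channel, centroids keep ``spec.min_separation`` apart (default
    4 sigma).  Against spots of *other* channels the clearance is at least
    6 sigma, so that two independently planted spots can never yield touching
    segmentation masks (each mask extends ~2 sigma) and planted colocalization
    counts stay unambiguous.  Placement modes: dispersed (uniform in the eroded
    ellipsoid), peripheral (normalized ellipsoidal radius in [0.75, 0.95]),
    clustered (isotropic Gaussian blobs around a few interior cluster centers).
    """
    center = (np.array(spec.shape) - 1) / 2.0 * np.array(spec.voxel_size)
    margin = 2.0 * spec.spot_sigma_um
    axes = np.maximum(np.array(spec.semi_axes_um) - margin, 1e-6)
    sep2 = spec.min_separation**2
    sep2_other = max(spec.min_separation, 6.0 * spec.spot_sigma_um) ** 2
    placed: list[np.ndarray] = []
    other_pts = list(other or [])

    if spec.placement == "clustered":
        centers = []
        while len(centers) < spec.n_clusters:
            u = rng.uniform(-0.6, 0.6, size=3)
            if (u**2).sum() <= 0.36:
                centers.append(center + u * axes)

    attempts = 0
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        if spec.placement == "dispersed":
            u = rng.uniform(-1, 1, size=3)
            if (u**2).sum() > 1.0:
                continue
            pt = center + u * axes
        elif spec.placement == "peripheral":
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            r = rng.uniform(0.75, 0.95)
            pt = center + r * v * axes
        else:  # clustered
            c = centers[rng.integers(len(centers))]
            pt = c + rng.normal(scale=3.0 * spec.spot_sigma_um, size=3)
            rel = (pt - center) / axes
            if (rel**2).sum() > 1.0:
                continue
        if placed and min(((pt - q) ** 2).sum() for q in placed) < sep2:
            continue
        if other_pts and min(((pt - q) ** 2).sum() for q in other_pts) < sep2_other:
            continue
        placed.append(pt)
    if len(placed) < n:
        raise SpotPlacementError(n - len(placed), n)
    return np.array(placed).reshape(n, 3)


def render_spot_field(
    shape: tuple[int, int, int],
    voxel_size: Sequence[float],
    centroids_um: np.ndarray,
    sigma_um: float | np.ndarray,
    amplitude: float | np.ndarray,
) -> np.ndarray:
    """Render isotropic-in-µm Gaussian spots onto the anisotropic voxel grid."""
    field_ = np.zeros(shape)
    centroids_um = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    if centroids_um.size == 0:
        return field_
    n = centroids_um.shape[0]
    sigmas = np.broadcast_to(np.asarray(sigma_um, dtype=float), (n,))
    amps = np.broadcast_to(np.asarray(amplitude, dtype=float), (n,))
    vs = np.asarray(voxel_size, dtype=float)
    for c, s, a in zip(centroids_um, sigmas, amps):
        lo = np.maximum(np.floor((c - 4 * s) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((c + 4 * s) / vs).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [np.arange(lo[i], hi[i]) * vs[i] - c[i] for i in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        )
        field_[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += a * np.exp(-d2 / (2 * s**2))
    return field_


# ---------------------------------------------------------------------------
# Main generators


def generate_nucleus_volume(spec: NucleusSimSpec) -> tuple[dict[str, VolumeImage], GroundTruth]:
    """Generate one multichannel synthetic nucleus and its ground truth.

    Returns a channel-name → VolumeImage dict (always containing "dapi") and a
    GroundTruth with the planted spot table, compaction label field, ellipsoid
    mask and the true colocalizing spot count.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.shape, spec.voxel_size, spec.semi_axes_um)

    # DAPI: Potts-coupled compaction classes with strictly increasing means
    comp = sample_potts_labels(mask, spec.n_classes, spec.beta, rng)
    class_means = spec.class_mean_base + spec.class_mean_step * np.arange(spec.n_classes)
    dapi_clean = np.full(spec.shape, spec.background, dtype=float)
    dapi_clean[mask] = class_means[comp[mask] - 1]

    # Spot placement: colocalized probe spots reuse target centroids exactly
    order = list(spec.n_spots)
    if spec.coloc_pair is not None:
        probe, target = spec.coloc_pair
        for name in (probe, target):
            if name not in spec.n_spots:
                raise ValueError(f"colocalization channel {name!r} has no n_spots entry")
        order = [target] + [c for c in order if c != target]

    centroids: dict[str, np.ndarray] = {}
    coloc_flags: dict[str, np.ndarray] = {}
    n_coloc = 0
    for name in order:
        n = int(spec.n_spots[name])
        flags = np.zeros(n, dtype=bool)
        other = [p for c, arr in centroids.items() if c != name for p in arr]
        if spec.coloc_pair is not None and name == spec.coloc_pair[0]:
            target_pts = centroids[spec.coloc_pair[1]]
            n_shared = int(round(spec.coloc_fraction * n))
            n_shared = min(n_shared, len(target_pts))
            idx = rng.choice(len(target_pts), size=n_shared, replace=False)
            shared = target_pts[idx]
            rest = _place_points(spec, n - n_shared, rng, other)
            pts = np.vstack([shared, rest]) if n else np.empty((0, 3))
            flags[:n_shared] = True
            n_coloc = n_shared
        else:
            pts = _place_points(spec, n, rng, other)
        centroids[name] = pts
        coloc_flags[name] = flags

    # Render channels
    clean: dict[str, np.ndarray] = {"dapi": dapi_clean}
    for name in spec.n_spots:
        f = render_spot_field(spec.shape, spec.voxel_size, centroids[name], spec.spot_sigma_um, spec.spot_amplitude)
        clean[name] = f + spec.background

    amplitudes = {name: np.full(len(centroids[name]), spec.spot_amplitude) for name in spec.n_spots}
    if spec.edu_pcna_ratio is not None and "edu" in clean and "pcna" in clean:
        pcna_total = (clean["pcna"] - spec.background).sum()
        edu_total = (clean["edu"] - spec.background).sum()
        if edu_total > 0:
            scale = spec.edu_pcna_ratio * pcna_total / edu_total
            clean["edu"] = (clean["edu"] - spec.background) * scale + spec.background
            amplitudes["edu"] *= scale

    channels: dict[str, VolumeImage] = {}
    for name, arr in clean.items():
        noisy = arr
        if spec.poisson:
            noisy = rng.poisson(np.maximum(noisy, 0)).astype(float)
        if spec.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sd, size=arr.shape)
        channels[name] = VolumeImage(noisy, spec.voxel_size, channel=name)

    rows = []
    for name in spec.n_spots:
        for i, (pt, cf) in enumerate(zip(centroids[name], coloc_flags[name])):
            rows.append(
                {
                    "channel": name,
                    "spot": i,
                    "z_um": pt[0],
                    "y_um": pt[1],
                    "x_um": pt[2],
                    "sigma_um": spec.spot_sigma_um,
                    "amplitude": amplitudes[name][i],
                    "colocalized": bool(cf),
                }
            )
    spots = pd.DataFrame(
        rows, columns=["channel", "spot", "z_um", "y_um", "x_um", "sigma_um", "amplitude", "colocalized"]
    )
    truth = GroundTruth(spots=spots, compaction=comp, mask=mask, n_colocalizing=n_coloc)
    return channels, truth


def generate_population(
    n_cells: int,
    fractions: Sequence[float] = (0.4, 0.4, 0.2),
    seed: int = 0,
    dapi_g1_mean: float = 1000.0,
    dapi_cv: float = 0.05,
    edu_positive_mean: float = 500.0,
    edu_positive_sd: float = 50.0,
    edu_negative_mean: float = 20.0,
    edu_negative_sd: float = 5.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a 2D-screen cell population with planted G1/S/G2 phases.

    ``fractions`` are (G1, S, G2) and must sum to 1; class counts are exact
    (largest-remainder rounding), the per-cell assignment is then shuffled.
    DAPI sums are drawn around 1x (G1), 2x (G2) and uniformly-interpolated
    DNA content for S cells; only S cells are EdU-positive.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or np.any(fr < 0):
        raise ValueError("fractions must be three non-negative numbers (G1, S, G2)")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("G1/S/G2 fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.floor(fr * n_cells).astype(int)
    rem = n_cells - counts.sum()
    if rem:
        frac_part = fr * n_cells - np.floor(fr * n_cells)
        for i in np.argsort(-frac_part)[:rem]:
            counts[i] += 1
    phases = np.repeat(np.array(["G1", "S", "G2"]), counts)
    rng.shuffle(phases)

    content = np.empty(n_cells)
    content[phases == "G1"] = 1.0
    content[phases == "G2"] = 2.0
    content[phases == "S"] = rng.uniform(1.05, 1.95, size=(phases == "S").sum())
    dapi = rng.normal(content * dapi_g1_mean, dapi_cv * content * dapi_g1_mean)
    edu = np.where(
        phases == "S",
        rng.normal(edu_positive_mean, edu_positive_sd, size=n_cells),
        rng.normal(edu_negative_mean, edu_negative_sd, size=n_cells),
    )
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "dapi_sum": np.maximum(dapi, 0.0),
            "edu": np.maximum(edu, 0.0),
        }
    )
    truth_df = df.assign(true_phase=phases)
    return df, GroundTruth(cells=truth_df)


def generate_origin_bed(
    n_per_chrom: Mapping[str, int],
    gap_sampler: Callable[[np.random.Generator, int], np.ndarray] | Sequence[float] | None = None,
    seed: int = 0,
    peak_width: int = 300,
    start_offset: int = 10_000,
):
    """Generate sorted, non-overlapping origin intervals with known gap structure.

    ``gap_sampler`` is either a sequence of fixed mid-to-mid gaps (bp, cycled),
    a callable ``(rng, size) -> gaps``, or None for the default lognormal with
    ~34 kb mean (typical unclustered inter-origin spacing).  Returns
    (OriginSet, GroundTruth) where the truth holds per-chromosome mids/gaps.
    """
    from .origins import OriginSet

    rng = np.random.default_rng(seed)
    rows = []
    gap_rows = []
    for chrom, n in n_per_chrom.items():
        if n <= 0:
            continue
        if n == 1:
            gaps = np.empty(0)
        elif gap_sampler is None:
            gaps = rng.lognormal(mean=np.log(30_000), sigma=0.5, size=n - 1)
        elif callable(gap_sampler):
            gaps = np.asarray(gap_sampler(rng, n - 1), dtype=float)
        else:
            seq = np.asarray(gap_sampler, dtype=float)
            gaps = np.resize(seq, n - 1)
        if np.any(gaps <= 0):
            raise ValueError("gaps must be positive")
        gaps = np.round(gaps).astype(int)
        if np.any(gaps < peak_width):
            raise ValueError(
                "mid-to-mid gaps smaller than the peak width would overlap; "
                "reduce peak_width or increase the gaps"
            )
        mids = start_offset + np.concatenate([[0], np.cumsum(gaps)])
        half = peak_width // 2
        for m in mids:
            rows.append((chrom, int(m - half), int(m - half + peak_width)))
        for g, m0, m1 in zip(mids[1:] - mids[:-1], mids[:-1], mids[1:]):
            gap_rows.append({"chrom": chrom, "mid_left": int(m0), "mid_right": int(m1), "gap": int(g)})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    origin_set = OriginSet.from_frame(df)
    truth = GroundTruth(gaps=pd.DataFrame(gap_rows, columns=["chrom", "mid_left", "mid_right", "gap"]))
    return origin_set, truth
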