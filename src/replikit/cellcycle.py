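"""High-throughput cell-cycle profiling and duration arithmetic.

A pulse of the thymidine analog EdU separates replicating (S-phase) from
non-replicating cells; DAPI sum intensity reports total DNA content and splits
the non-replicating cells into G1 (1x DNA) and G2 (2x DNA).  Phase fractions
combined with the culture doubling time give absolute phase durations:

    dt = (log 2 * Δt) / (log N2 - log N1)
    duration_phase = fraction_phase * dt

Logs are natural; the ratio makes the base cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .core import VolumeImage

PHASES = ("G1", "S", "G2")


@dataclass(frozen=True)
class GrowthObservation:
    """Two cell counts N1, N2 taken Δt hours apart during log-phase growth."""

    n1: float
    n2: float
    delta_t_h: float

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("cell counts must be positive")
        if self.delta_t_h <= 0:
            raise ValueError("Δt must be positive")


def doubling_time(obs: GrowthObservation) -> float:
    """Culture doubling time in hours: dt = (log 2 × Δt) / (log N2 − log N1)."""
    if obs.n2 <= obs.n1:
        raise ValueError("N2 must exceed N1: population is not growing")
    return float(np.log(2.0) * obs.delta_t_h / (np.log(obs.n2) - np.log(obs.n1)))


def phase_durations(fractions: Mapping[str, float], dt_h: float) -> dict[str, float]:
    """Hours spent in each phase (or S sub-stage): duration_i = fraction_i × dt.

    Fractions must each lie in [0, 1] and sum to at most 1 (a subset of phases
    may be given, e.g. the S I/S II/S III split of the S-phase duration).
    """
    vals = np.array(list(fractions.values()), dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if vals.sum() > 1 + 1e-9:
        raise ValueError("fractions sum to more than 1")
    return {k: float(v) * dt_h for k, v in fractions.items()}


def project_sum(volume: VolumeImage) -> np.ndarray:
    """Sum-projection over z (float output, no clipping)."""
    if volume.data.shape[0] < 1 or volume.data.size == 0:
        raise ValueError("volume has no z-planes")
    return volume.data.astype(float).sum(axis=0)


def segment_nuclei_2d(
    image: np.ndarray,
    min_area: int = 50,
    max_area: int | None = None,
    sigma: float = 2.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Label nuclei in a 2D projection.

    Gaussian smoothing, Otsu threshold (or an explicit one), distance-transform
    watershed to split touching nuclei, then an area filter.  Returns an int
    label map (0 = background); an empty map is a valid result.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    smoothed = gaussian(image, sigma=sigma, preserve_range=True)
    if threshold is None:
        if np.ptp(smoothed) == 0:
            return np.zeros(image.shape, dtype=np.int32)
        threshold = threshold_otsu(smoothed)
    fg = smoothed > threshold
    if not fg.any():
        return np.zeros(image.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(dist, labels=cc_label(fg), min_distance=int(max(3, sigma * 2)), exclude_border=False)
    markers = np.zeros(image.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers=markers, mask=fg)
    out = np.zeros_like(labels)
    nxt = 1
    for lab in range(1, labels.max() + 1):
        area = int((labels == lab).sum())
        if area < min_area or (max_area is not None and area > max_area):
            continue
        out[labels == lab] = nxt
        nxt += 1
    return out


def measure_nuclei(image_dapi: np.ndarray, image_edu: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-nucleus DAPI and EdU sum intensities from a 2D label map."""
    ids = np.arange(1, labels.max() + 1)
    if len(ids) == 0:
        return pd.DataFrame(columns=["cell_id", "dapi_sum", "edu"])
    dapi = ndimage.sum_labels(image_dapi, labels, index=ids)
    edu = ndimage.sum_labels(image_edu, labels, index=ids)
    return pd.DataFrame({"cell_id": ids, "dapi_sum": dapi, "edu": edu})


def _histogram_modes(values: np.ndarray, bins: int = 64) -> np.ndarray:
    """Centers of prominent histogram modes, ordered by decreasing height.

    The histogram is lightly smoothed and peaks must be prominent (>= 10% of
    the tallest bin) so shot noise in bin counts does not masquerade as a mode.
    """
    from scipy.signal import find_peaks

    hist, edges = np.histogram(values, bins=bins)
    smooth = ndimage.uniform_filter1d(hist.astype(float), size=3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, _ = find_peaks(np.concatenate([[0.0], smooth, [0.0]]), prominence=0.1 * smooth.max())
    idx = peaks - 1
    return centers[idx[np.argsort(-smooth[idx])]]


def gate_cell_cycle(
    records: pd.DataFrame,
    edu_threshold: float | str = "auto",
    dapi_cutoff: float | str = "auto",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assign G1/S/G2 phases from EdU and DAPI sum intensities.

    Cells with EdU above the threshold are S; the rest are split at a DAPI
    cutoff between the 1x and 2x DNA-content modes.  Automatic EdU threshold:
    Otsu on log(1+EdU).  Automatic DAPI cutoff: midpoint of the two largest
    histogram modes of the non-S cells (an error suggests manual cutoffs if
    the histogram is unimodal).  Returns (records + ``phase`` column, phase
    fractions summing to 1).
    """
    df = records.copy()
    if df["dapi_sum"].lt(0).any() or df["edu"].lt(0).any():
        raise ValueError("intensities must be non-negative")
    auto = edu_threshold == "auto" or dapi_cutoff == "auto"
    if auto and len(df) < 20:
        raise ValueError("automatic thresholding needs at least 20 cells")
    if edu_threshold == "auto":
        edu_threshold = float(np.expm1(threshold_otsu(np.log1p(df["edu"].to_numpy()))))
    is_s = df["edu"].to_numpy() > float(edu_threshold)

    non_s_dapi = df.loc[~is_s, "dapi_sum"].to_numpy()
    if dapi_cutoff == "auto":
        if len(non_s_dapi) == 0:
            dapi_cutoff = float("inf")
        else:
            modes = _histogram_modes(non_s_dapi)
            if len(modes) < 2 or max(modes[:2]) / min(modes[:2]) < 1.3:
                # G2 cells carry ~2x the G1 DNA content; anything closer is one mode
                raise ValueError(
                    "DAPI histogram of non-S cells is unimodal; pass a manual dapi_cutoff"
                )
            m1, m2 = sorted(modes[:2])
            dapi_cutoff = 0.5 * (m1 + m2)
    phase = np.where(is_s, "S", np.where(df["dapi_sum"].to_numpy() <= float(dapi_cutoff), "G1", "G2"))
    df["phase"] = phase
    n = len(df)
    fractions = {p: float((phase == p).sum()) / n for p in PHASES}
    return df, fractions


def phase_fraction_table(records: pd.DataFrame) -> pd.Series:
    """Phase fractions from a gated record table (convenience)."""
    return records["phase"].value_counts(normalize=True).reindex(PHASES, fill_value=0.0)
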