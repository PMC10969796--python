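"""Ratiometric fork-speed proxy: nucleotide incorporation per active replisome.

A 15-min EdU pulse measures nucleotides incorporated; PCNA marks active
replisomes at fixation.  The ratio R = total EdU / total PCNA signal inside
the nucleus therefore scales with DNA synthesized per replisome: R > 1 reads
as faster forks, R <= 1 as slower forks (EdU confined within PCNA).  Raw
ratios are comparable only after dividing by a normalization-group median
(per cell line by default), which cancels channel gains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import NucleusMask, VolumeImage


def _background_level(data: np.ndarray, mask: np.ndarray, foci: np.ndarray | None) -> float:
    """Per-channel background: mode (histogram peak) of outside-foci voxels inside the mask."""
    sel = mask.copy()
    if foci is not None:
        sel &= ~(np.asarray(foci) > 0)
    vals = data[sel]
    if vals.size == 0:
        return 0.0
    hist, edges = np.histogram(vals, bins=128)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def fork_ratio(
    edu: VolumeImage,
    pcna: VolumeImage,
    mask: NucleusMask,
    mode: str = "sum",
    edu_foci: np.ndarray | None = None,
    pcna_foci: np.ndarray | None = None,
    subtract_background: bool = True,
) -> float:
    """Raw EdU/PCNA ratio for one nucleus.

    mode "sum": R = Σ EdU / Σ PCNA over (background-subtracted) voxels inside
    the nucleus mask.  mode "volume": R = segmented EdU volume / segmented
    PCNA volume, taking ``edu_foci``/``pcna_foci`` label maps from the 3D spot
    segmentation of each channel.
    """
    if edu.data.shape != pcna.data.shape or edu.data.shape != mask.data.shape:
        raise ValueError("EdU, PCNA and mask must share a shape")
    if mode == "volume":
        if edu_foci is None or pcna_foci is None:
            raise ValueError("volume mode needs segmented label maps for both channels")
        v_edu = float((np.asarray(edu_foci) > 0).sum())
        v_pcna = float((np.asarray(pcna_foci) > 0).sum())
        if v_pcna <= 0:
            raise ValueError("no active replisomes detected (empty PCNA segmentation)")
        return v_edu / v_pcna
    if mode != "sum":
        raise ValueError(f"unknown mode {mode!r}")

    m = mask.data
    e = edu.data.astype(float)
    p = pcna.data.astype(float)
    if subtract_background:
        e = e - _background_level(e, m, edu_foci)
        p = p - _background_level(p, m, pcna_foci)
    total_e = float(np.maximum(e, 0.0)[m].sum())
    total_p = float(np.maximum(p, 0.0)[m].sum())
    if total_p <= 0:
        raise ValueError("no active replisomes detected (Σ PCNA <= 0)")
    return total_e / total_p


def normalize_ratios(ratios: pd.DataFrame, group_keys=("cell_line",)) -> pd.DataFrame:
    """Divide each raw ratio by its normalization-group median.

    ``ratios`` needs a ``ratio`` column plus the grouping columns.  The median
    of the normalized values is exactly 1 within every group, which makes the
    statistic invariant to global EdU and PCNA gains.
    """
    if "ratio" not in ratios.columns:
        raise ValueError("expected a 'ratio' column")
    group_keys = [k for k in group_keys if k in ratios.columns]
    df = ratios.copy()
    if not group_keys:
        med = float(df["ratio"].median())
        if not np.isfinite(med) or med <= 0 or df.empty:
            raise ValueError("cannot normalize an empty or degenerate group")
        df["normalized_ratio"] = df["ratio"] / med
        return df

    def _norm(g: pd.DataFrame) -> pd.DataFrame:
        med = float(g["ratio"].median())
        if g.empty or not np.isfinite(med) or med <= 0:
            raise ValueError("cannot normalize an empty or degenerate group")
        return g.assign(normalized_ratio=g["ratio"] / med)

    return df.groupby(list(group_keys), group_keys=False)[df.columns].apply(_norm).reset_index(drop=True)


def stage_medians(ratios: pd.DataFrame, value: str = "normalized_ratio") -> pd.Series:
    """Median (normalized) ratio per S-phase sub-stage, in S I → S III order."""
    med = ratios.groupby("stage")[value].median()
    order = [s for s in ("SI", "SII", "SIII") if s in med.index]
    return med.reindex(order) if order else med
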