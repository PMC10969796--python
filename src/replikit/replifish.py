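"""Repli-FISH replication-timing measurements.

Replication timing of repeat sequences (rDNA, centromeres, Alu, LINE1) is read
out by intersecting binary masks of FISH probe signals with binary masks of
replication foci ("AND" logic): connected components of the voxelwise
conjunction are the repeats replicating at fixation time.  Probe intensity
within the RFi masks, normalized to the early-S (S I) median, gives a
fold-change timing profile; a third mask (RPA 194, active rDNA transcription)
yields the fraction of replicating repeats that are also transcribing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ColocResult:
    """Connected components of the voxelwise AND of two masks."""

    labels: np.ndarray
    n_objects: int
    volumes_um3: np.ndarray
    fraction_replicating: float  # fraction of probe (mask_a) objects with an intersection


def _as_binary(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask) > 0


def and_colocalize(mask_a: np.ndarray, mask_b: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> ColocResult:
    """Voxelwise AND of two binary masks; 26-connected components are counted.

    ``mask_a`` is the probe mask for the ``fraction_replicating`` statistic
    (fraction of probe objects with at least one intersecting voxel).
    """
    a, b = _as_binary(mask_a), _as_binary(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = a & b
    labels, n = ndimage.label(inter, structure=_STRUCT26)
    voxvol = float(np.prod(voxel_size))
    volumes = (
        ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1)) * voxvol
        if n
        else np.empty(0)
    )
    a_labels, n_a = ndimage.label(a, structure=_STRUCT26)
    if n_a:
        hit = np.unique(a_labels[inter])
        frac = float(len(hit[hit > 0])) / n_a
    else:
        frac = 0.0
    return ColocResult(labels=labels, n_objects=int(n), volumes_um3=np.asarray(volumes), fraction_replicating=frac)


def replicating_repeat_count(probe_labels: np.ndarray, rfi_labels: np.ndarray) -> int:
    """Number of repeat copies replicating: components of AND(probe, RFi)."""
    return and_colocalize(_as_binary(probe_labels), _as_binary(rfi_labels)).n_objects


def triple_association(
    rdna_labels: np.ndarray,
    rfi_labels: np.ndarray,
    rpa_labels: np.ndarray,
    tolerance_dilations: int = 0,
) -> tuple[int, int, float]:
    """Association of replicating rDNA with RNA Pol I (RPA 194).

    Replicating rDNA = components of AND(rDNA, RFi); a component is
    "associated" when it shares >= 1 voxel with the RPA mask (optionally after
    dilating the RPA mask ``tolerance_dilations`` times to absorb registration
    slack).  Returns (n_replicating, n_associated, fraction).
    """
    rep = and_colocalize(_as_binary(rdna_labels), _as_binary(rfi_labels))
    if rep.n_objects == 0:
        return 0, 0, 0.0
    rpa = _as_binary(rpa_labels)
    if rpa.shape != rep.labels.shape:
        raise ValueError("RPA mask shape mismatch")
    if tolerance_dilations:
        rpa = ndimage.binary_dilation(rpa, iterations=tolerance_dilations)
    hit = np.unique(rep.labels[rpa])
    n_assoc = int(len(hit[hit > 0]))
    return rep.n_objects, n_assoc, n_assoc / rep.n_objects


def probe_timing_profile(
    measurements: pd.DataFrame,
    reference_stage: str = "SI",
    drop_zero: bool = False,
) -> pd.DataFrame:
    """Fold-change replication-timing profile from probe-in-RFi intensities.

    ``measurements`` needs columns cell_id, probe, stage, and ``probe_in_rfi``
    (sum probe intensity over the RFi voxels of that cell; optionally a
    cell_line column defining extra normalization groups).  Each value is
    divided by the median over the reference stage of its probe (x cell line)
    group, so the reference-stage median fold change is 1 by construction.
    Cells with zero probe-in-RFi signal are kept unless ``drop_zero``.
    """
    df = measurements.copy()
    required = {"cell_id", "probe", "stage", "probe_in_rfi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if drop_zero:
        df = df[df["probe_in_rfi"] > 0]
    group_cols = ["probe"] + (["cell_line"] if "cell_line" in df.columns else [])

    def _norm(g: pd.DataFrame) -> pd.DataFrame:
        ref = g.loc[g["stage"] == reference_stage, "probe_in_rfi"]
        if ref.empty:
            raise ValueError(
                f"no {reference_stage} cells for group {tuple(g[c].iloc[0] for c in group_cols)}: "
                "reference median undefined"
            )
        med = float(ref.median())
        if med == 0:
            raise ValueError("reference median is zero; cannot normalize")
        return g.assign(fold_change=g["probe_in_rfi"] / med)

    out = df.groupby(group_cols, group_keys=False)[df.columns].apply(_norm)
    return out.reset_index(drop=True)


def probe_intensity_in_rfi(probe_volume: np.ndarray, rfi_labels: np.ndarray) -> float:
    """Sum probe intensity over RFi voxels (a single cell's measurement)."""
    return float(np.asarray(probe_volume, dtype=float)[_as_binary(rfi_labels)].sum())
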