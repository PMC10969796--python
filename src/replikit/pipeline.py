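"""Top-level per-cell pipeline driver.

Runs nucleus segmentation → channel masking → spot segmentation, then the
configured analyses (repli-FISH colocalization, fork-speed ratio, compaction
classification) for every cell, collecting one long-format tidy CSV per
analysis plus a run manifest (config hash, versions, seed).  Per-cell
failures are logged and skipped; the run fails only if every cell fails.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, compaction as compaction_mod, foci3d, forkspeed as forkspeed_mod
from . import nucleus3d, replifish
from .config import PipelineConfig
from .core import VolumeImage

log = logging.getLogger(__name__)


@dataclass
class CellInput:
    """One cell: channel-name → VolumeImage, plus optional annotations."""

    cell_id: str
    channels: dict[str, VolumeImage]
    stage: str = ""
    cell_line: str = ""


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)


def _get_channel(cell: CellInput, config: PipelineConfig, role: str) -> VolumeImage:
    name = config.channels[role]
    if name not in cell.channels:
        raise KeyError(f"cell {cell.cell_id}: channel {name!r} (role {role!r}) missing")
    return cell.channels[name]


def run_pipeline(config: PipelineConfig, cells: list[CellInput], write: bool = True) -> PipelineResult:
    """Execute the configured analyses on every cell.

    With ``write`` the tidy CSVs and ``manifest.json`` land in
    ``config.output_dir``; the returned PipelineResult carries them either way.
    """
    per_analysis: dict[str, list[pd.DataFrame]] = {a: [] for a in config.analyses}
    spot_rows: list[pd.DataFrame] = []
    failures: list[str] = []
    for cell in cells:
        try:
            rows = _run_cell(config, cell)
        except Exception as exc:  # per-cell isolation is deliberate
            log.error("cell %s failed: %s", cell.cell_id, exc)
            failures.append(cell.cell_id)
            continue
        for analysis, df in rows.items():
            if analysis == "spots":
                spot_rows.append(df)
            else:
                per_analysis[analysis].append(df)
    if len(failures) == len(cells) and cells:
        raise RuntimeError(f"all {len(cells)} cells failed; first failure: {failures[0]}")

    tables = {}
    if spot_rows:
        tables["spots"] = pd.concat(spot_rows, ignore_index=True)
    for analysis, frames in per_analysis.items():
        if frames:
            tables[analysis] = pd.concat(frames, ignore_index=True)
    if "forkspeed" in tables:
        tables["forkspeed"] = forkspeed_mod.normalize_ratios(tables["forkspeed"], group_keys=("cell_line",))

    manifest = {
        "replikit_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_cells": len(cells),
        "n_failed": len(failures),
        "analyses": list(config.analyses),
    }
    if write:
        out = config.ensure_output_dir()
        config.to_yaml(out / "config.yaml")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return PipelineResult(tables=tables, manifest=manifest, failures=failures)


def _run_cell(config: PipelineConfig, cell: CellInput) -> dict[str, pd.DataFrame]:
    dapi = _get_channel(cell, config, "dapi")
    mask = nucleus3d.segment_nucleus_3d(
        dapi,
        sigma_px=config.nucleus_sigma_px,
        dilations=config.nucleus_dilations,
        erosions=config.nucleus_erosions,
    )
    rfi_vol = nucleus3d.mask_channel(_get_channel(cell, config, "rfi"), mask)
    spots = foci3d.segment_spots(
        rfi_vol,
        mask=mask.data,
        k=config.k,
        sigma0_um=config.spot_sigma0_um,
        use_watershed=config.use_watershed,
        min_voxels=config.min_voxels,
        h=config.seed_h,
    )
    meta = {"cell_id": cell.cell_id, "stage": cell.stage, "cell_line": cell.cell_line}
    out: dict[str, pd.DataFrame] = {}

    feats = foci3d.spot_features(spots, mask)
    out["spots"] = feats.table.assign(**meta)
    if "foci" in config.analyses:
        out["foci"] = pd.DataFrame(
            [
                {
                    **meta,
                    "n_spots": feats.n_spots,
                    "mean_volume_um3": float(np.mean(feats.volumes_um3)) if feats.n_spots else np.nan,
                    "mean_pair_distance_um": float(np.mean(feats.pair_distances_um))
                    if len(feats.pair_distances_um)
                    else np.nan,
                    "mean_border_distance_um": float(np.mean(feats.border_distances_um))
                    if feats.n_spots
                    else np.nan,
                }
            ]
        )
    if "replifish" in config.analyses:
        probe_vol = nucleus3d.mask_channel(_get_channel(cell, config, "probe"), mask)
        probe_spots = foci3d.segment_spots(
            probe_vol,
            mask=mask.data,
            k=config.k,
            sigma0_um=config.spot_sigma0_um,
            use_watershed=config.use_watershed,
            min_voxels=config.min_voxels,
            h=config.seed_h,
        )
        coloc = replifish.and_colocalize(probe_spots.binary(), spots.binary(), voxel_size=config.voxel_size)
        out["replifish"] = pd.DataFrame(
            [
                {
                    **meta,
                    "n_probe": probe_spots.n_objects,
                    "n_rfi": spots.n_objects,
                    "n_colocalizing": coloc.n_objects,
                    "fraction_replicating": coloc.fraction_replicating,
                    "probe_in_rfi": replifish.probe_intensity_in_rfi(probe_vol.data, spots.labels),
                }
            ]
        )
    if "forkspeed" in config.analyses:
        edu_vol = nucleus3d.mask_channel(_get_channel(cell, config, "edu"), mask)
        pcna_vol = nucleus3d.mask_channel(_get_channel(cell, config, "pcna"), mask)
        ratio = forkspeed_mod.fork_ratio(edu_vol, pcna_vol, mask)
        out["forkspeed"] = pd.DataFrame([{**meta, "ratio": ratio}])
    if "compaction" in config.analyses:
        cmap = compaction_mod.classify_compaction(
            dapi, mask.data, n_classes=config.n_classes, beta=config.beta
        )
        profile = compaction_mod.map_signal_to_classes(rfi_vol, spots.binary(), cmap)
        frame = cmap.as_frame().assign(signal_fraction=profile.fractions, **meta)
        out["compaction"] = frame
    return out
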