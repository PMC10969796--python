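"""Pipeline configuration: validated parameters for every analysis step."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import DEFAULT_VOXEL_SIZE


@dataclass
class PipelineConfig:
    """All tunable parameters of the per-cell pipeline.

    ``channels`` maps analysis roles (dapi, rfi, probe, edu, pcna, rpa, ...)
    to channel names in the input data; every role an enabled analysis needs
    must be mapped.  Lengths are µm, windows bp.
    """

    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channels: dict = field(default_factory=lambda: {"dapi": "dapi", "rfi": "pcna"})
    analyses: tuple = ("foci",)  # subset of {foci, replifish, forkspeed, compaction}
    # nucleus3d
    nucleus_sigma_px: float = 2.0
    nucleus_dilations: int = 2
    nucleus_erosions: int = 2
    # foci3d
    k: float = 2.0
    spot_sigma0_um: float = 0.25
    seed_h: float | None = None
    min_voxels: int = 5
    use_watershed: bool = True
    # compaction
    n_classes: int = 7
    beta: float = 1.0
    # origins
    windows: tuple = (10_000, 20_000, 30_000)
    # bookkeeping
    output_dir: str = "replikit_out"
    seed: int = 0
    quantize_8bit: bool = False

    _ROLE_REQUIREMENTS = {
        "foci": ("dapi", "rfi"),
        "replifish": ("dapi", "rfi", "probe"),
        "forkspeed": ("dapi", "edu", "pcna"),
        "compaction": ("dapi", "rfi"),
    }

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        unknown = set(self.analyses) - set(self._ROLE_REQUIREMENTS)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        for analysis in self.analyses:
            missing = [r for r in self._ROLE_REQUIREMENTS[analysis] if r not in self.channels]
            if missing:
                raise ValueError(f"analysis {analysis!r} needs channel roles {missing} mapped")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "voxel_size" in raw:
            raw["voxel_size"] = tuple(raw["voxel_size"])
        for key in ("analyses", "windows"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        d["analyses"] = list(self.analyses)
        d["windows"] = list(self.windows)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration for the run manifest."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def ensure_output_dir(self) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p
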