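"""Run configuration, manifests and provenance records for the pipeline CLI.

Every pipeline step writes a ``manifest.json`` into its output directory:
the sha256 checksum of each artifact plus a snapshot of the configuration
and seeds that produced it. A manifest plus its config snapshot is enough to
re-run the step; identical configs and seeds give byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .fcnn import FCNNConfig

__all__ = ["RunConfig", "sha256_file", "write_manifest", "read_manifest"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end experiment.

    Loaded from a single YAML file; individual CLI flags override fields.
    All randomness flows from the named seeds recorded here.
    """

    schema: str = "A"
    n_per_phantom: int = 24000
    train_fraction: float = 0.75
    slice_policy: str = "first_half"
    voi_radius: int = 15
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise: bool = True
    scene_seed: int = 0
    sampling_seed: int = 1
    training_seed: int = 2
    signal_table: str | None = None  # path to a SequenceSignalTable JSON
    tissues: tuple[str, ...] = (
        "Skin",
        "Muscle",
        "Adipose",
        "Spongiosa",
        "45% HA bone",
        "Brain",
        "Liver",
    )
    fcnn: FCNNConfig = field(default_factory=FCNNConfig)

    def __post_init__(self) -> None:
        if self.schema not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown model schema {self.schema!r}")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        if self.n_per_phantom < 1:
            raise ValueError("n_per_phantom must be >= 1")
        if isinstance(self.fcnn, dict):
            self.fcnn = FCNNConfig(**self.fcnn)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "voxel_spacing" in raw:
            raw["voxel_spacing"] = tuple(raw["voxel_spacing"])
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_spacing"] = list(self.voxel_spacing)
        d["tissues"] = list(self.tissues)
        return d


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(directory: str | Path, config: dict, artifacts: list[str | Path]) -> Path:
    """Write ``manifest.json`` listing artifact checksums and the config snapshot."""
    directory = Path(directory)
    manifest = {
        "config": config,
        "artifacts": {
            str(Path(a).relative_to(directory)): sha256_file(a) for a in artifacts
        },
    }
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_manifest(directory: str | Path) -> dict:
    return json.loads((Path(directory) / "manifest.json").read_text())
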