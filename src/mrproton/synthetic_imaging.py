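"""Synthetic phantom scenes: voxelized geometry and rendered MR / DECT-surrogate volumes.

The simulator emulates the bench setup used to calibrate the regressors: a
cylindrical deionized-water container (84.1 mm radius, 254 mm height) holding
rectangular tissue-substitute inserts of 57 x 57 x 129 mm^3. Each MR sequence
is rendered by looking up a per-tissue nominal, water-relative signal and
adding noise scaled so the water region attains a configured SNR; DECT
material-decomposition output is emulated directly as relative electron
density and effective atomic number maps computed from the tissue
compositions, with multiplicative noise at the published decomposition error
scale (0.8% for rho_e, 2.9% for Z_eff).

Per-tissue nominal MR signals are not physically simulated; the default
:data:`DEFAULT_SIGNAL_TABLE` encodes the qualitative contrasts of the real
sequences (adipose bright on the Dixon fat channel, the 45% hydroxyapatite
mix bright on T1-Dixon and dark on T2-STIR, mineral-bearing mixes bright on
ZTE) with well-separated numeric stand-ins. Everything is overridable.

Axis convention: arrays are indexed ``(slice, row, column)`` = (z, y, x),
zero-based, voxel centers at integer index times spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

from .tissue_data import (
    TissueSpec,
    effective_atomic_number,
    relative_electron_density,
    water_spec,
)

__all__ = [
    "AIR_ID",
    "WATER_ID",
    "PhantomSceneConfig",
    "SequenceSignalTable",
    "DEFAULT_SIGNAL_TABLE",
    "DEFAULT_SEQUENCES",
    "LabelMap",
    "VolumeImage",
    "ParametricMaps",
    "build_scene",
    "render_sequence",
    "render_parametric_maps",
    "ground_truth_maps",
    "default_study_scenes",
    "save_volume",
    "load_volume",
]

AIR_ID = 0
WATER_ID = 1

DEFAULT_SEQUENCES = ("T1-D-P-W", "T1-D-P-F", "T2-STIR", "ZTE")


@dataclass(frozen=True)
class PhantomSceneConfig:
    """Geometry and channel layout of one phantom-in-cylinder scene.

    ``inserts`` is a list of ``(tissue name, (dx, dy))`` pairs giving the
    in-plane center offset of each insert from the cylinder axis, in mm;
    inserts are centered axially.
    """

    container_radius: float = 84.1
    container_height: float = 254.0
    insert_dims: tuple[float, float, float] = (57.0, 57.0, 129.0)  # (x, y, z) mm
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x) mm
    inserts: tuple[tuple[str, tuple[float, float]], ...] = ()
    sequences: tuple[str, ...] = DEFAULT_SEQUENCES
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be > 0 on all axes")
        if self.container_radius <= 0 or self.container_height <= 0:
            raise ValueError("container dimensions must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSceneConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["inserts"] = tuple(
            (name, tuple(offset)) for name, offset in raw.get("inserts", [])
        )
        for key in ("insert_dims", "voxel_spacing", "sequences"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "container_radius": self.container_radius,
            "container_height": self.container_height,
            "insert_dims": list(self.insert_dims),
            "voxel_spacing": list(self.voxel_spacing),
            "inserts": [[name, list(off)] for name, off in self.inserts],
            "sequences": list(self.sequences),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass(frozen=True)
class SequenceSignalTable:
    """Nominal water-relative signal per (tissue, sequence), plus noise levels.

    Water has signal 1.0 in every sequence by construction (it is the
    normalization reference). ``snr`` maps sequence name to the water-region
    signal-to-noise ratio; noise sigma is water signal / SNR. ``raw_scale``
    sets the arbitrary scanner-units level of the water signal in rendered
    (un-normalized) volumes.
    """

    nominal_signal: Mapping[tuple[str, str], float]
    snr: Mapping[str, float] = field(default_factory=dict)
    noise_model: str = "gaussian"
    raw_scale: float = 600.0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for (tissue, seq), v in self.nominal_signal.items():
            if v < 0:
                raise ValueError(f"negative nominal signal for ({tissue}, {seq})")
        for seq, s in self.snr.items():
            if s <= 0:
                raise ValueError(f"SNR must be > 0 for {seq}")

    def signal(self, tissue: str, sequence: str) -> float:
        if tissue == "Water":
            return 1.0
        key = (tissue, sequence)
        if key not in self.nominal_signal:
            raise KeyError(f"no nominal signal for (tissue={tissue!r}, sequence={sequence!r})")
        return self.nominal_signal[key]

    def sequence_snr(self, sequence: str) -> float:
        return self.snr.get(sequence, 30.0)

    def to_json(self, path: str | Path) -> None:
        d = {
            "nominal_signal": {f"{t}|{s}": v for (t, s), v in self.nominal_signal.items()},
            "snr": dict(self.snr),
            "noise_model": self.noise_model,
            "raw_scale": self.raw_scale,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SequenceSignalTable":
        d = json.loads(Path(path).read_text())
        nominal = {tuple(k.split("|")): v for k, v in d["nominal_signal"].items()}
        return cls(
            nominal_signal=nominal,
            snr=d.get("snr", {}),
            noise_model=d.get("noise_model", "gaussian"),
            raw_scale=d.get("raw_scale", 600.0),
        )


def _default_signals() -> dict[tuple[str, str], float]:
    #              T1-D-P-W  T1-D-P-F  T2-STIR  ZTE
    rows = {
        "Skin":        (1.45, 0.25, 1.70, 0.55),
        "Muscle":      (1.20, 0.50, 1.30, 0.50),
        "Adipose":     (0.30, 2.20, 0.30, 0.80),
        "Spongiosa":   (0.75, 1.50, 0.70, 1.40),
        "45% HA bone": (1.70, 0.30, 0.15, 1.80),
        "Brain":       (0.95, 0.75, 1.95, 0.45),
        "Liver":       (1.00, 0.65, 1.45, 0.60),
        "Water":       (1.00, 1.00, 1.00, 1.00),
    }
    return {
        (tissue, seq): val
        for tissue, vals in rows.items()
        for seq, val in zip(DEFAULT_SEQUENCES, vals)
    }


#: Default contrast table. SNR 30 on every sequence (the floor observed on
#: the real acquisitions, at which noise-induced degradation is negligible).
DEFAULT_SIGNAL_TABLE = SequenceSignalTable(
    nominal_signal=_default_signals(),
    snr={seq: 30.0 for seq in DEFAULT_SEQUENCES},
)


@dataclass(frozen=True)
class LabelMap:
    """Voxelized scene: integer tissue ids on a regular grid.

    ``legend`` maps id -> tissue name; 0 is air, 1 is water.
    """

    grid: np.ndarray  # (z, y, x) int16
    spacing: tuple[float, float, float]
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        present = set(np.unique(self.grid).tolist())
        missing = present - set(self.legend) - {AIR_ID}
        if missing:
            raise ValueError(f"label ids without legend entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    @property
    def n_slices(self) -> int:
        return self.grid.shape[0]

    def id_of(self, tissue: str) -> int:
        for i, name in self.legend.items():
            if name == tissue:
                return i
        raise KeyError(f"tissue {tissue!r} not in legend")

    def tissue_ids(self) -> list[int]:
        """Ids of phantom inserts (excludes air and water)."""
        return sorted(i for i in self.legend if i not in (AIR_ID, WATER_ID))

    def mask(self, tissue_id: int) -> np.ndarray:
        return self.grid == tissue_id

    def container_mask(self) -> np.ndarray:
        return self.grid != AIR_ID

    def save(self, path: str | Path, legend_path: str | Path | None = None) -> None:
        save_volume(
            VolumeImage(self.grid.astype(np.int16), self.spacing, channel="labels"),
            path,
        )
        if legend_path is not None:
            Path(legend_path).write_text(
                json.dumps({str(k): v for k, v in self.legend.items()}, indent=2)
            )

    @classmethod
    def load(cls, path: str | Path, legend_path: str | Path) -> "LabelMap":
        vol = load_volume(path, channel="labels")
        legend = {
            int(k): v for k, v in json.loads(Path(legend_path).read_text()).items()
        }
        return cls(grid=np.asarray(vol.grid, dtype=np.int16), spacing=vol.spacing, legend=legend)


@dataclass(frozen=True)
class VolumeImage:
    """A single-channel 3-D image with voxel spacing metadata."""

    grid: np.ndarray  # (z, y, x)
    spacing: tuple[float, float, float]
    channel: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(np.asarray(self.grid, dtype=np.float64))):
            raise ValueError(f"non-finite values in volume {self.channel!r}")


@dataclass(frozen=True)
class ParametricMaps:
    """DECT-surrogate parametric maps: relative electron density and Z_eff."""

    rho_e: VolumeImage
    z_eff: VolumeImage


def _insert_bounds(
    config: PhantomSceneConfig, offset: tuple[float, float]
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
    """Physical (z, y, x) bounds of an insert box, in mm from the cylinder axis
    (x, y) and from the container bottom (z)."""
    dx_half, dy_half, dz_half = (
        config.insert_dims[0] / 2,
        config.insert_dims[1] / 2,
        config.insert_dims[2] / 2,
    )
    cz = config.container_height / 2
    ox, oy = offset
    return (
        (cz - dz_half, cz + dz_half),
        (oy - dy_half, oy + dy_half),
        (ox - dx_half, ox + dx_half),
    )


def build_scene(
    config: PhantomSceneConfig, tissues: Mapping[str, TissueSpec] | Sequence[str]
) -> LabelMap:
    """Voxelize a phantom scene into a :class:`LabelMap`.

    Voxels inside an insert box get that tissue's id (2, 3, ... in insert
    order), remaining voxels inside the cylinder get the water id, voxels
    outside the cylinder are air. Raises on overlapping inserts, inserts
    that poke out of the container, or insert tissues missing from
    ``tissues``.
    """
    if not config.inserts:
        raise ValueError("scene must contain at least one insert")
    known = set(tissues.keys()) if isinstance(tissues, Mapping) else set(tissues)
    sz, sy, sx = config.voxel_spacing
    R, H = config.container_radius, config.container_height
    # voxel centers at integer index * spacing; half-open insert intervals so
    # a 57 mm box at 1 mm spacing spans exactly 57 voxels
    nz = max(int(round(H / sz)), 1)
    ny = int(np.floor(2 * R / sy)) + 1
    nx = int(np.floor(2 * R / sx)) + 1
    z = np.arange(nz) * sz
    y = np.arange(ny) * sy - (ny - 1) * sy / 2
    x = np.arange(nx) * sx - (nx - 1) * sx / 2
    in_cyl = (y[:, None] ** 2 + x[None, :] ** 2) <= R**2
    grid = np.zeros((nz, ny, nx), dtype=np.int16)
    grid[:, in_cyl] = WATER_ID

    # validate geometry before rasterizing
    half_diag = []
    for name, offset in config.inserts:
        if name not in known:
            raise KeyError(f"insert tissue {name!r} has no spec")
        (z0, z1), (y0, y1), (x0, x1) = _insert_bounds(config, offset)
        corner_r = max(
            np.hypot(yc, xc) for yc in (y0, y1) for xc in (x0, x1)
        )
        if corner_r > R or z0 < 0 or z1 > H:
            raise ValueError(f"insert {name!r} extends outside the container")
        half_diag.append((name, (z0, z1), (y0, y1), (x0, x1)))
    for i in range(len(half_diag)):
        for j in range(i + 1, len(half_diag)):
            _, zi, yi, xi = half_diag[i]
            _, zj, yj, xj = half_diag[j]
            if (
                zi[0] < zj[1] and zj[0] < zi[1]
                and yi[0] < yj[1] and yj[0] < yi[1]
                and xi[0] < xj[1] and xj[0] < xi[1]
            ):
                raise ValueError(
                    f"inserts {half_diag[i][0]!r} and {half_diag[j][0]!r} overlap"
                )

    legend: dict[int, str] = {WATER_ID: "Water"}
    for k, (name, (z0, z1), (y0, y1), (x0, x1)) in enumerate(half_diag):
        tid = 2 + k
        legend[tid] = name
        zm = (z >= z0) & (z < z1)
        ym = (y >= y0) & (y < y1)
        xm = (x >= x0) & (x < x1)
        box = zm[:, None, None] & ym[None, :, None] & xm[None, None, :]
        grid[box & (grid == WATER_ID)] = tid  # only where in-cylinder water
    return LabelMap(grid=grid, spacing=(sz, sy, sx), legend=legend)


def render_sequence(
    labels: LabelMap,
    table: SequenceSignalTable,
    sequence: str,
    seed: int | None = 0,
    noise: bool = True,
) -> VolumeImage:
    """Render one MR channel from a label map and a signal table.

    The noiseless image is a per-tissue lookup of nominal signal times
    ``raw_scale`` (air renders as 0). With ``noise=True``, Gaussian noise of
    sigma = water signal / SNR is added everywhere (or Rician magnitude noise
    when the table says so). Bit-identical for identical inputs and seed.
    """
    lut = np.zeros(max(labels.legend) + 1, dtype=np.float64)
    for tid, name in labels.legend.items():
        lut[tid] = table.signal(name, sequence) * table.raw_scale
    img = lut[labels.grid]
    if noise:
        rng = np.random.default_rng(seed)
        sigma = table.raw_scale / table.sequence_snr(sequence)
        if table.noise_model == "gaussian":
            img = img + rng.normal(0.0, sigma, size=img.shape)
        else:  # rician: magnitude of complex signal with iid gaussian parts
            re = img + rng.normal(0.0, sigma, size=img.shape)
            im = rng.normal(0.0, sigma, size=img.shape)
            img = np.hypot(re, im)
    return VolumeImage(
        grid=img.astype(np.float32), spacing=labels.spacing, channel=sequence
    )


def render_parametric_maps(
    labels: LabelMap,
    specs: Mapping[str, TissueSpec],
    noise: tuple[float, float] | None = (0.008, 0.029),
    seed: int | None = 0,
    z_eff_exponent: float = 3.1,
) -> ParametricMaps:
    """Emulate DECT material-decomposition output for a scene.

    Per-tissue relative electron density is computed from composition and
    measured density; Z_eff from the power-law mixture rule. ``noise`` gives
    fractional (multiplicative Gaussian) sigma for (rho_e, z_eff); the
    defaults match the published mean decomposition errors (0.8%, 2.9%).
    Air voxels are set to 0 in both maps.
    """
    specs = dict(specs)
    specs.setdefault("Water", water_spec())
    rho_lut = np.zeros(max(labels.legend) + 1)
    zeff_lut = np.zeros(max(labels.legend) + 1)
    for tid, name in labels.legend.items():
        if name not in specs:
            raise KeyError(f"no tissue spec for {name!r}")
        spec = specs[name]
        rho_lut[tid] = relative_electron_density(spec, spec.measured_density)
        zeff_lut[tid] = effective_atomic_number(spec, exponent=z_eff_exponent)
    rho = rho_lut[labels.grid]
    zeff = zeff_lut[labels.grid]
    if noise is not None:
        rng = np.random.default_rng(seed)
        inside = labels.container_mask()
        rho = rho * np.where(inside, 1.0 + noise[0] * rng.normal(size=rho.shape), 1.0)
        zeff = zeff * np.where(inside, 1.0 + noise[1] * rng.normal(size=zeff.shape), 1.0)
    return ParametricMaps(
        rho_e=VolumeImage(rho.astype(np.float32), labels.spacing, channel="rho-e"),
        z_eff=VolumeImage(zeff.astype(np.float32), labels.spacing, channel="z-eff"),
    )


def ground_truth_maps(
    labels: LabelMap, specs: Mapping[str, TissueSpec]
) -> tuple[VolumeImage, VolumeImage]:
    """Per-voxel ground-truth (mass density g/cm^3, RSP) maps.

    Values are the measured density and RSP of each tissue spec; water is
    (1.000, 1.000); air voxels are 0.
    """
    specs = dict(specs)
    specs.setdefault("Water", water_spec())
    dens_lut = np.zeros(max(labels.legend) + 1)
    rsp_lut = np.zeros(max(labels.legend) + 1)
    for tid, name in labels.legend.items():
        if name not in specs:
            raise KeyError(f"no tissue spec for {name!r}")
        dens_lut[tid] = specs[name].measured_density
        rsp_lut[tid] = specs[name].measured_rsp
    return (
        VolumeImage(dens_lut[labels.grid], labels.spacing, channel="density"),
        VolumeImage(rsp_lut[labels.grid], labels.spacing, channel="rsp"),
    )


def default_study_scenes(
    tissue_names: Sequence[str] = (
        "Skin",
        "Muscle",
        "Adipose",
        "Spongiosa",
        "45% HA bone",
        "Brain",
        "Liver",
    ),
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    sequences: tuple[str, ...] = DEFAULT_SEQUENCES,
    seed: int = 0,
) -> list[PhantomSceneConfig]:
    """Scene configs for the default calibration study.

    Seven inserts cannot fit in one cylinder cross-section, so the study
    uses two cylinders (four + three inserts) with inserts on a 2 x 2 grid
    whose corners stay inside the 84.1 mm radius.
    """
    offsets = [(-28.6, -28.6), (28.6, -28.6), (-28.6, 28.6), (28.6, 28.6)]
    scenes = []
    for start in range(0, len(tissue_names), 4):
        group = tissue_names[start : start + 4]
        scenes.append(
            PhantomSceneConfig(
                voxel_spacing=voxel_spacing,
                inserts=tuple((name, offsets[i]) for i, name in enumerate(group)),
                sequences=tuple(sequences),
                seed=seed + start,
            )
        )
    return scenes


def save_volume(volume: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with spacing encoded in the affine.

    Array axes (z, y, x) are stored transposed to NIfTI's (x, y, z) order.
    """
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    data = np.ascontiguousarray(np.transpose(np.asarray(volume.grid), (2, 1, 0)))
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_volume(path: str | Path, channel: str = "", normalized: bool = False) -> VolumeImage:
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return VolumeImage(grid=data, spacing=spacing, channel=channel, normalized=normalized)
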