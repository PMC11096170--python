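"""Water normalization, VOI voxel extraction, dataset splitting, matrix assembly.

The training currency of the regressors is a :class:`VoxelTable`: an N x k
matrix of water-normalized channel intensities with per-voxel density / RSP
targets, tissue labels and provenance. This module builds those tables from
rendered (or acquired) channel stacks under the anti-leakage protocol used
throughout the package: the first half of the slices feeds training, the
second half is reserved for application/evaluation, and the training rows
are split 75/25 into fit and validation partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_imaging import WATER_ID, LabelMap, VolumeImage, ground_truth_maps
from .tissue_data import TissueSpec

__all__ = [
    "VOI",
    "VoxelTable",
    "normalize_by_water",
    "water_mask",
    "voi_for_insert",
    "voi_mask",
    "first_half_slices",
    "second_half_slices",
    "application_mask",
    "extract_voi_voxels",
    "extract_study_table",
    "split_train_val",
]


@dataclass(frozen=True)
class VOI:
    """Circular volume of interest inside one phantom insert.

    In-plane disc of ``radius`` voxels around ``center`` (row, column voxel
    coordinates), over the inclusive slice interval ``slice_range``.
    """

    center: tuple[float, float]
    radius: int = 15
    slice_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("VOI radius must be > 0")
        if self.slice_range[1] < self.slice_range[0]:
            raise ValueError("empty VOI slice range")


@dataclass
class VoxelTable:
    """N x k channel matrix with targets, labels and provenance.

    ``channels`` holds water-normalized intensities, one column per sequence
    in ``channel_names`` order. ``provenance`` is a DataFrame with columns
    ``phantom``, ``scene``, ``slice``, ``voxel`` (flat index into the scene
    grid) identifying where each row came from.
    """

    channels: np.ndarray
    channel_names: tuple[str, ...]
    density: np.ndarray
    rsp: np.ndarray
    tissue: np.ndarray
    provenance: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.channels)
        if self.channels.ndim != 2 or self.channels.shape[1] != len(self.channel_names):
            raise ValueError("channel matrix width must match channel_names")
        for name, col in (("density", self.density), ("rsp", self.rsp), ("tissue", self.tissue)):
            if len(col) != n:
                raise ValueError(f"column {name} has length {len(col)}, expected {n}")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("non-finite channel values")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    def target(self, quantity: str) -> np.ndarray:
        if quantity == "density":
            return self.density
        if quantity == "rsp":
            return self.rsp
        raise KeyError(f"unknown target quantity {quantity!r}")

    def select(self, idx: np.ndarray) -> "VoxelTable":
        return VoxelTable(
            channels=self.channels[idx],
            channel_names=self.channel_names,
            density=self.density[idx],
            rsp=self.rsp[idx],
            tissue=self.tissue[idx],
            provenance=self.provenance.iloc[idx].reset_index(drop=True)
            if self.provenance is not None
            else None,
        )

    def restrict_channels(self, names: Sequence[str]) -> "VoxelTable":
        """Project onto a channel subset (e.g. a model schema)."""
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(f"channels not in table: {missing}; have {self.channel_names}")
        cols = [self.channel_names.index(n) for n in names]
        return VoxelTable(
            channels=self.channels[:, cols],
            channel_names=tuple(names),
            density=self.density,
            rsp=self.rsp,
            tissue=self.tissue,
            provenance=self.provenance,
        )

    @staticmethod
    def concat(tables: Sequence["VoxelTable"]) -> "VoxelTable":
        names = tables[0].channel_names
        if any(t.channel_names != names for t in tables):
            raise ValueError("cannot concatenate tables with different channel schemas")
        return VoxelTable(
            channels=np.concatenate([t.channels for t in tables]),
            channel_names=names,
            density=np.concatenate([t.density for t in tables]),
            rsp=np.concatenate([t.rsp for t in tables]),
            tissue=np.concatenate([t.tissue for t in tables]),
            provenance=pd.concat(
                [t.provenance for t in tables], ignore_index=True
            )
            if all(t.provenance is not None for t in tables)
            else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.channels, columns=list(self.channel_names))
        df["density"] = self.density
        df["rsp"] = self.rsp
        df["tissue"] = self.tissue
        if self.provenance is not None:
            for c in self.provenance.columns:
                df[c] = self.provenance[c].to_numpy()
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, channel_names: Sequence[str]) -> "VoxelTable":
        df = pd.read_csv(path)
        prov_cols = [c for c in ("phantom", "scene", "slice", "voxel") if c in df.columns]
        return cls(
            channels=df[list(channel_names)].to_numpy(dtype=np.float64),
            channel_names=tuple(channel_names),
            density=df["density"].to_numpy(dtype=np.float64),
            rsp=df["rsp"].to_numpy(dtype=np.float64),
            tissue=df["tissue"].to_numpy(dtype=object),
            provenance=df[prov_cols] if prov_cols else None,
        )


def water_mask(labels: LabelMap) -> np.ndarray:
    """Boolean mask of water-labeled voxels (the normalization reference)."""
    return labels.grid == WATER_ID


def normalize_by_water(image: VolumeImage, mask: np.ndarray) -> VolumeImage:
    """Divide an image by its mean value over the water mask.

    The normalized water region has mean 1 (to within floating-point
    round-off), making channel values comparable across scans regardless of
    scanner scaling. Idempotent up to the same tolerance.
    """
    if mask.shape != image.grid.shape:
        raise ValueError("water mask shape does not match image")
    if not mask.any():
        raise ValueError("empty water mask")
    ref = float(np.asarray(image.grid, dtype=np.float64)[mask].mean())
    if ref <= 0:
        raise ValueError(f"non-positive water reference value {ref}")
    return VolumeImage(
        grid=np.asarray(image.grid, dtype=np.float64) / ref,
        spacing=image.spacing,
        channel=image.channel,
        normalized=True,
    )


def first_half_slices(n_slices: int) -> range:
    """Training slice set: ``[0, floor(S/2))``; odd S gives the extra slice
    to the application half. Raises for single-slice volumes."""
    if n_slices < 2:
        raise ValueError("cannot halve a volume with fewer than 2 slices")
    return range(0, n_slices // 2)


def second_half_slices(n_slices: int) -> range:
    """Application slice set: ``[floor(S/2), S)``."""
    if n_slices < 2:
        raise ValueError("cannot halve a volume with fewer than 2 slices")
    return range(n_slices // 2, n_slices)


def application_mask(labels: LabelMap) -> np.ndarray:
    """Boolean grid mask selecting all voxels on application (second-half) slices."""
    mask = np.zeros(labels.shape, dtype=bool)
    mask[labels.n_slices // 2 :] = True
    return mask


def voi_for_insert(labels: LabelMap, tissue: str, radius: int = 15) -> VOI:
    """VOI centered on an insert's in-plane centroid, spanning its slices."""
    tid = labels.id_of(tissue)
    zz, yy, xx = np.nonzero(labels.grid == tid)
    if len(zz) == 0:
        raise ValueError(f"tissue {tissue!r} has no voxels in this scene")
    return VOI(
        center=(float(yy.mean()), float(xx.mean())),
        radius=radius,
        slice_range=(int(zz.min()), int(zz.max())),
    )


def voi_mask(labels: LabelMap, tissue: str, voi: VOI, slices: Sequence[int] | None = None) -> np.ndarray:
    """Boolean mask of VOI voxels of one phantom, optionally restricted to a slice set.

    The in-plane disc is intersected with the tissue's own label mask so a
    VOI can never leak into water or a neighboring insert.
    """
    tid = labels.id_of(tissue)
    nz, ny, nx = labels.shape
    yy, xx = np.ogrid[:ny, :nx]
    disc = (yy - voi.center[0]) ** 2 + (xx - voi.center[1]) ** 2 <= voi.radius**2
    mask = (labels.grid == tid) & disc[None, :, :]
    allowed = np.zeros(nz, dtype=bool)
    lo, hi = voi.slice_range
    allowed[lo : hi + 1] = True
    if slices is not None:
        chosen = np.zeros(nz, dtype=bool)
        chosen[list(slices)] = True
        allowed &= chosen
    mask &= allowed[:, None, None]
    return mask


def _slice_set(n_slices: int, policy: str) -> Sequence[int]:
    if policy == "first_half":
        return first_half_slices(n_slices)
    if policy == "second_half":
        return second_half_slices(n_slices)
    if policy == "all":
        return range(n_slices)
    raise ValueError(f"unknown slice policy {policy!r}")


def extract_voi_voxels(
    images: Sequence[VolumeImage],
    labels: LabelMap,
    specs: Mapping[str, TissueSpec],
    n_per_phantom: int = 24000,
    slice_policy: str = "first_half",
    radius: int = 15,
    seed: int | None = 0,
    vois: Mapping[str, VOI] | None = None,
    scene: str = "scene0",
) -> VoxelTable:
    """Sample VOI voxels of every insert in one scene into a VoxelTable.

    Exactly ``n_per_phantom`` rows per insert are drawn uniformly without
    replacement from the VOI voxels on the slices allowed by
    ``slice_policy`` (``first_half`` for training, ``second_half`` for
    application evaluation, ``all`` for the patient-style schemas). Rows
    carry the ground-truth density/RSP of the insert's tissue spec and full
    provenance. Deterministic per seed.
    """
    for img in images:
        if not img.normalized:
            raise ValueError(f"channel {img.channel!r} is not water-normalized")
        if img.grid.shape != labels.shape:
            raise ValueError(f"channel {img.channel!r} grid differs from label grid")
    channel_names = tuple(img.channel for img in images)
    density_map, rsp_map = ground_truth_maps(labels, specs)
    slices = _slice_set(labels.n_slices, slice_policy)
    rng = np.random.default_rng(seed)
    stack = np.stack([np.asarray(img.grid, dtype=np.float64).reshape(-1) for img in images], axis=1)
    tables = []
    for tid in labels.tissue_ids():
        name = labels.legend[tid]
        voi = (vois or {}).get(name) or voi_for_insert(labels, name, radius=radius)
        mask = voi_mask(labels, name, voi, slices=slices)
        flat = np.flatnonzero(mask.reshape(-1))
        if len(flat) < n_per_phantom:
            raise ValueError(
                f"phantom {name!r}: only {len(flat)} VOI voxels available on "
                f"{slice_policy} slices, {n_per_phantom} requested "
                f"(short by {n_per_phantom - len(flat)})"
            )
        chosen = np.sort(rng.choice(flat, size=n_per_phantom, replace=False))
        slice_idx = chosen // (labels.shape[1] * labels.shape[2])
        tables.append(
            VoxelTable(
                channels=stack[chosen],
                channel_names=channel_names,
                density=density_map.grid.reshape(-1)[chosen],
                rsp=rsp_map.grid.reshape(-1)[chosen],
                tissue=np.full(n_per_phantom, name, dtype=object),
                provenance=pd.DataFrame(
                    {
                        "phantom": name,
                        "scene": scene,
                        "slice": slice_idx,
                        "voxel": chosen,
                    }
                ),
            )
        )
    return VoxelTable.concat(tables)


def extract_study_table(
    scene_data: Sequence[tuple[Sequence[VolumeImage], LabelMap]],
    specs: Mapping[str, TissueSpec],
    n_per_phantom: int = 24000,
    slice_policy: str = "first_half",
    radius: int = 15,
    seed: int | None = 0,
) -> VoxelTable:
    """Assemble one table over several scenes (phantom cylinders)."""
    tables = [
        extract_voi_voxels(
            images,
            labels,
            specs,
            n_per_phantom=n_per_phantom,
            slice_policy=slice_policy,
            radius=radius,
            seed=None if seed is None else seed + i,
            scene=f"scene{i}",
        )
        for i, (images, labels) in enumerate(scene_data)
    ]
    return VoxelTable.concat(tables)


def split_train_val(
    table: VoxelTable, train_fraction: float = 0.75, seed: int | None = 0
) -> tuple[VoxelTable, VoxelTable]:
    """Random disjoint-and-exhaustive split, stratified per phantom.

    ``round(n_phantom * train_fraction)`` rows of each phantom go to the
    training partition, the rest to validation; deterministic per seed.
    """
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx = []
    val_idx = []
    for name in pd.unique(pd.Series(table.tissue)):
        idx = np.flatnonzero(table.tissue == name)
        perm = rng.permutation(idx)
        n_train = int(round(len(idx) * train_fraction))
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx)) if any(len(v) for v in val_idx) else np.array([], dtype=int)
    return table.select(train_idx), table.select(val_idx)
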