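"""Voxel-wise regressors: FCNN models A-D, a linear baseline, DECT conversions.

Four channel schemas are exercised:

====== ============================================== ==================
Model  Input channels                                 Targets
====== ============================================== ==================
A      T1-D-P-W, T1-D-P-F, T2-STIR                    density, RSP
B      T1-D-P-W, T1-D-P-F, T2-STIR, ZTE               density, RSP
C      T1-D-P-W, T2-STIR                              density
D      T1-D-P-W, T2-STIR, rho-e, z-eff                density
====== ============================================== ==================

Model C's channel pair is configurable (clinical datasets differ in which
second MR channel is available); Model D replaces the learned synthetic-DECT
channels of a full clinical pipeline with DECT-surrogate parametric maps.

Alongside the learned models this module implements the two reference
conversions applied to DECT parametric maps — an affine electron-density to
mass-density fit and a piecewise-in-Z_eff RSP formula — and a single-channel
ordinary-least-squares baseline on the T1-Dixon water image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fcnn import FCNN, FCNNConfig
from .preprocessing import VoxelTable
from .synthetic_imaging import VolumeImage

__all__ = [
    "ModelSchema",
    "SCHEMAS",
    "RegressorBundle",
    "train_fcnn",
    "train_bundle",
    "predict_table",
    "predict_map",
    "LinearModel",
    "linear_baseline",
    "dect_empirical_density",
    "dect_empirical_rsp",
]


@dataclass(frozen=True)
class ModelSchema:
    """Named channel layout and target list of one regressor family."""

    name: str
    channels: tuple[str, ...]
    targets: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return len(self.channels)


SCHEMAS: dict[str, ModelSchema] = {
    "A": ModelSchema("A", ("T1-D-P-W", "T1-D-P-F", "T2-STIR"), ("density", "rsp")),
    "B": ModelSchema("B", ("T1-D-P-W", "T1-D-P-F", "T2-STIR", "ZTE"), ("density", "rsp")),
    "C": ModelSchema("C", ("T1-D-P-W", "T2-STIR"), ("density",)),
    "D": ModelSchema("D", ("T1-D-P-W", "T2-STIR", "rho-e", "z-eff"), ("density",)),
}


def train_fcnn(
    train: VoxelTable,
    val: VoxelTable | None,
    config: FCNNConfig,
    target: str = "density",
    epochs: int | None = None,
) -> FCNN:
    """Train one single-target FCNN on a voxel table.

    Only the training partition drives the parameter updates; the validation
    table is evaluated per epoch for the loss history.
    """
    if len(train) == 0:
        raise ValueError("empty training table")
    model = FCNN(n_inputs=train.n_channels, n_outputs=1, config=config)
    model.fit(
        train.channels,
        train.target(target),
        X_val=val.channels if val is not None and len(val) else None,
        y_val=val.target(target) if val is not None and len(val) else None,
        epochs=epochs,
    )
    return model


@dataclass
class RegressorBundle:
    """Trained density / RSP regressors sharing one channel schema.

    With ``joint=True`` a single two-output network serves both targets;
    by default density and RSP are separate single-output networks (their
    losses are defined independently).
    """

    schema: ModelSchema
    config: FCNNConfig
    density_model: FCNN | None = None
    rsp_model: FCNN | None = None
    joint_model: FCNN | None = None

    @property
    def channel_schema(self) -> tuple[str, ...]:
        return self.schema.channels

    @property
    def training_history(self) -> dict[str, dict[str, list[float]]]:
        out = {}
        if self.joint_model is not None:
            out["joint"] = self.joint_model.history
        if self.density_model is not None:
            out["density"] = self.density_model.history
        if self.rsp_model is not None:
            out["rsp"] = self.rsp_model.history
        return out

    def predict(self, channels: np.ndarray, target: str) -> np.ndarray:
        if target not in self.schema.targets:
            raise KeyError(f"schema {self.schema.name} does not model {target!r}")
        if channels.ndim != 2 or channels.shape[1] != self.schema.n_channels:
            raise ValueError(
                f"model {self.schema.name} expects channels {self.schema.channels}; "
                f"got a matrix of shape {channels.shape}"
            )
        if self.joint_model is not None:
            col = self.schema.targets.index(target)
            return self.joint_model.predict(channels)[:, col]
        model = self.density_model if target == "density" else self.rsp_model
        if model is None:
            raise RuntimeError(f"no trained model for target {target!r}")
        return model.predict(channels)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import json

        (directory / "schema.json").write_text(
            json.dumps(
                {
                    "name": self.schema.name,
                    "channels": list(self.schema.channels),
                    "targets": list(self.schema.targets),
                    "joint": self.joint_model is not None,
                },
                indent=2,
            )
        )
        if self.joint_model is not None:
            self.joint_model.save(directory / "joint")
        if self.density_model is not None:
            self.density_model.save(directory / "density")
        if self.rsp_model is not None:
            self.rsp_model.save(directory / "rsp")

    @classmethod
    def load(cls, directory: str | Path) -> "RegressorBundle":
        import json

        directory = Path(directory)
        meta = json.loads((directory / "schema.json").read_text())
        schema = ModelSchema(
            meta["name"], tuple(meta["channels"]), tuple(meta["targets"])
        )
        bundle = cls(schema=schema, config=None)
        if meta.get("joint"):
            bundle.joint_model = FCNN.load(directory / "joint")
            bundle.config = bundle.joint_model.config
        else:
            if (directory / "density.npz").exists():
                bundle.density_model = FCNN.load(directory / "density")
                bundle.config = bundle.density_model.config
            if (directory / "rsp.npz").exists():
                bundle.rsp_model = FCNN.load(directory / "rsp")
                bundle.config = bundle.rsp_model.config
        return bundle


def train_bundle(
    train: VoxelTable,
    val: VoxelTable | None,
    config: FCNNConfig,
    schema: ModelSchema | str = "A",
    joint: bool = False,
    epochs: int | None = None,
) -> RegressorBundle:
    """Train the density (and, for A/B schemas, RSP) regressors of one schema.

    The voxel tables are projected onto the schema's channel order first, so
    a wider extraction table can feed any schema.
    """
    schema = SCHEMAS[schema] if isinstance(schema, str) else schema
    tr = train.restrict_channels(schema.channels)
    va = val.restrict_channels(schema.channels) if val is not None and len(val) else None
    bundle = RegressorBundle(schema=schema, config=config)
    if joint:
        model = FCNN(n_inputs=schema.n_channels, n_outputs=len(schema.targets), config=config)
        y = np.stack([tr.target(t) for t in schema.targets], axis=1)
        yv = (
            np.stack([va.target(t) for t in schema.targets], axis=1)
            if va is not None
            else None
        )
        model.fit(tr.channels, y, X_val=va.channels if va is not None else None, y_val=yv, epochs=epochs)
        bundle.joint_model = model
        return bundle
    for i, target in enumerate(schema.targets):
        cfg = FCNNConfig(**{**config.__dict__, "seed": config.seed + i})
        model = train_fcnn(tr, va, cfg, target=target, epochs=epochs)
        if target == "density":
            bundle.density_model = model
        else:
            bundle.rsp_model = model
    return bundle


def predict_table(bundle: RegressorBundle, table: VoxelTable, target: str) -> np.ndarray:
    """Apply a bundle to a voxel table (projected onto the bundle's schema)."""
    return bundle.predict(table.restrict_channels(bundle.schema.channels).channels, target)


def predict_map(
    bundle: RegressorBundle,
    images: Sequence[VolumeImage],
    mask: np.ndarray,
    target: str = "density",
    sentinel: float = 0.0,
) -> VolumeImage:
    """Voxel-wise application of a trained bundle to a normalized channel stack.

    ``images`` must carry exactly the bundle's channels in schema order and
    the same water-normalization convention used at training time. Voxels
    outside ``mask`` are set to ``sentinel`` (0 by default, the same value
    used for air in ground-truth maps).
    """
    names = tuple(img.channel for img in images)
    if names != bundle.schema.channels:
        raise ValueError(
            f"channel stack {names} does not match model {bundle.schema.name} "
            f"schema {bundle.schema.channels}"
        )
    for img in images:
        if not img.normalized:
            raise ValueError(f"channel {img.channel!r} is not water-normalized")
    shape = images[0].grid.shape
    flat_mask = mask.reshape(-1)
    X = np.stack(
        [np.asarray(img.grid, dtype=np.float64).reshape(-1)[flat_mask] for img in images],
        axis=1,
    )
    out = np.full(int(np.prod(shape)), sentinel, dtype=np.float64)
    out[flat_mask] = bundle.predict(X, target)
    return VolumeImage(
        grid=out.reshape(shape),
        spacing=images[0].spacing,
        channel=f"{target}-model{bundle.schema.name}",
    )


# ---------------------------------------------------------------------------
# linear baseline


@dataclass(frozen=True)
class LinearModel:
    """Single-channel ordinary least squares: prediction = slope*signal + intercept."""

    slope: float
    intercept: float
    channel: str = "T1-D-P-W"

    def predict(self, signal: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(signal, dtype=np.float64) + self.intercept


def linear_baseline(
    table: VoxelTable, target: str = "density", channel: str = "T1-D-P-W"
) -> LinearModel:
    """Fit the single-channel linear comparison model by OLS."""
    s = table.restrict_channels([channel]).channels[:, 0]
    if np.ptp(s) == 0:
        raise ValueError(f"channel {channel!r} is constant; linear fit is degenerate")
    y = table.target(target)
    slope, intercept = np.polyfit(s, y, deg=1)
    return LinearModel(slope=float(slope), intercept=float(intercept), channel=channel)


# ---------------------------------------------------------------------------
# DECT empirical conversions


def dect_empirical_density(rho_e):
    """Mass density (g/cm^3) from relative electron density.

    ``rho = -0.1746 + 1.176 * rho_e``, applied element-wise. The affine fit
    can go negative at very low electron density; outputs are not clipped.
    """
    rho_e = np.asarray(rho_e, dtype=np.float64)
    if not np.all(np.isfinite(rho_e)):
        raise ValueError("non-finite rho_e input")
    out = -0.1746 + 1.176 * rho_e
    return float(out) if out.ndim == 0 else out


def dect_empirical_rsp(rho_e, z_eff):
    """Proton RSP from (relative electron density, effective atomic number).

    Piecewise in Z_eff over half-open intervals::

        [0, 0.5)   -> rho_e
        [0.5, 8.5) -> (1.1114 - 0.0148 Z_eff) * rho_e
        [8.5, 10)  -> 0.9905 * rho_e
        [10, inf)  -> (1.1117 - 0.0116 Z_eff) * rho_e

    Element-wise over arrays; scalar in, scalar out.
    """
    rho_e = np.asarray(rho_e, dtype=np.float64)
    z_eff = np.asarray(z_eff, dtype=np.float64)
    if not (np.all(np.isfinite(rho_e)) and np.all(np.isfinite(z_eff))):
        raise ValueError("non-finite input")
    if np.any(z_eff < 0):
        raise ValueError("negative Z_eff")
    factor = np.select(
        [z_eff < 0.5, z_eff < 8.5, z_eff < 10.0],
        [np.ones_like(z_eff), 1.1114 - 0.0148 * z_eff, np.full_like(z_eff, 0.9905)],
        default=1.1117 - 0.0116 * z_eff,
    )
    out = factor * rho_e
    return float(out) if out.ndim == 0 else out
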