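"""Absolute-percentage-error metrics, per-phantom reports and line profiles.

Model accuracy is summarized per phantom as the mean absolute percentage
error over evaluable voxels::

    APE_i = |x_i - x_i,REF| / |x_i,REF| * 100
    MAPE  = (1/N) sum_i APE_i

The "+/-" column of a report is the population standard deviation of the
per-voxel APE. Reports carry one row per (phantom, model, quantity) and are
rendered as tidy CSV/JSON or as a phantom x model text table. Line profiles
sample a volume at equispaced points along a segment with nearest-voxel
lookup (no interpolation), matching how profiles across tissue boundaries
are usually read.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_imaging import LabelMap, VolumeImage

__all__ = [
    "ape",
    "mape",
    "per_phantom_report",
    "report_from_table",
    "format_report",
    "line_profile",
]

REPORT_COLUMNS = ("phantom", "model", "quantity", "mape", "sd", "n", "n_negative")


def ape(x, ref):
    """Absolute percentage error, element-wise. ``ref`` must be nonzero."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if np.any(ref == 0):
        raise ValueError("zero reference value in APE")
    out = np.abs((x - ref) / ref) * 100.0
    return float(out) if out.ndim == 0 else out


def mape(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Mean and population SD of per-voxel APE, in percent."""
    pred = np.atleast_1d(np.asarray(pred, dtype=np.float64))
    ref = np.atleast_1d(np.asarray(ref, dtype=np.float64))
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    errors = ape(pred, ref)
    return float(errors.mean()), float(errors.std())


def _rows_per_phantom(pred, ref, tissue, model, quantity):
    rows = []
    for name in pd.unique(pd.Series(tissue)):
        sel = tissue == name
        m, sd = mape(pred[sel], ref[sel])
        rows.append(
            {
                "phantom": name,
                "model": model,
                "quantity": quantity,
                "mape": m,
                "sd": sd,
                "n": int(sel.sum()),
                "n_negative": int((pred[sel] < 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def per_phantom_report(
    pred_map: VolumeImage,
    truth_map: VolumeImage,
    labels: LabelMap,
    mask: np.ndarray,
    model: str,
    quantity: str,
) -> pd.DataFrame:
    """One MAPE +/- SD row per phantom over ``mask``-selected voxels.

    ``mask`` restricts evaluation (typically to application-slice VOI
    voxels). Phantoms with no evaluable voxel are omitted with a warning.
    ``n_negative`` counts non-physical negative predictions, which are
    reported rather than clipped.
    """
    if pred_map.grid.shape != truth_map.grid.shape or pred_map.grid.shape != labels.shape:
        raise ValueError("prediction, truth and label grids differ")
    frames = []
    for tid in labels.tissue_ids():
        name = labels.legend[tid]
        sel = (labels.grid == tid) & mask
        if not sel.any():
            warnings.warn(f"phantom {name!r}: no evaluable voxels, row omitted")
            continue
        frames.append(
            _rows_per_phantom(
                np.asarray(pred_map.grid, dtype=np.float64)[sel],
                np.asarray(truth_map.grid, dtype=np.float64)[sel],
                np.full(int(sel.sum()), name, dtype=object),
                model,
                quantity,
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(REPORT_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def report_from_table(
    pred: np.ndarray, table, model: str, quantity: str
) -> pd.DataFrame:
    """Per-phantom MAPE rows from predictions aligned with a VoxelTable."""
    return _rows_per_phantom(
        np.asarray(pred, dtype=np.float64),
        table.target(quantity),
        table.tissue,
        model,
        quantity,
    )


def format_report(report: pd.DataFrame, quantity: str) -> str:
    """Render a tidy report as a phantom x model text table (``MAPE +/- SD``)."""
    sub = report[report["quantity"] == quantity]
    cell = sub.apply(lambda r: f"{r['mape']:.2f} ± {r['sd']:.2f}", axis=1)
    wide = pd.DataFrame(
        {"phantom": sub["phantom"], "model": sub["model"], "cell": cell}
    ).pivot(index="phantom", columns="model", values="cell")
    return f"MAPE (%) for {quantity}\n" + wide.to_string()


def line_profile(
    volume: VolumeImage,
    start: Sequence[float],
    end: Sequence[float],
    n_samples: int = 50,
) -> pd.DataFrame:
    """Sample a volume along a segment at ``n_samples`` equispaced points.

    ``start`` and ``end`` are (slice, row, column) voxel coordinates; values
    are nearest-voxel lookups. Returns a DataFrame with ``position`` (mm
    along the segment) and ``value`` columns.
    """
    start = np.asarray(start, dtype=np.float64)
    end = np.asarray(end, dtype=np.float64)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if np.allclose(start, end):
        raise ValueError("degenerate segment: start equals end")
    shape = np.asarray(volume.grid.shape)
    for pt, label in ((start, "start"), (end, "end")):
        if np.any(pt < 0) or np.any(pt > shape - 1):
            raise ValueError(f"{label} point {pt.tolist()} outside the volume")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    idx = np.clip(np.rint(pts).astype(int), 0, shape - 1)
    values = np.asarray(volume.grid)[idx[:, 0], idx[:, 1], idx[:, 2]]
    spacing = np.asarray(volume.spacing)
    seg_mm = np.linalg.norm((end - start) * spacing)
    return pd.DataFrame({"position": t * seg_mm, "value": values})
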