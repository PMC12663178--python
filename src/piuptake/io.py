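"""Readers and writers for the pipeline's on-disk formats.

Trace tables are wide CSVs — cell metadata columns followed by one column
per frame named ``t_<seconds>`` — so synthetic and extracted traces share a
schema and either can feed the kinetics stage.  Image stacks are multi-page
16-bit TIFFs with a JSON sidecar holding the physical metadata (pixel size,
frame interval, acquisition delay, bubble radius, cavitation center).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import ImageStack, TraceSet

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_truth_csv",
    "write_stack",
    "read_stack",
    "write_labels",
    "read_labels",
]

_TIME_PREFIX = "t_"


def write_traces_csv(path, traces: TraceSet, cells: pd.DataFrame | None = None) -> None:
    """Write a wide trace CSV: metadata columns then ``t_<s>`` frame columns.

    ``cells`` optionally supplies per-cell metadata (x_um, y_um, gamma, ...)
    aligned with ``traces.cell_ids``.
    """
    meta = pd.DataFrame({"cell_id": traces.cell_ids})
    if cells is not None:
        extra = cells.set_index("cell_id").loc[traces.cell_ids].reset_index()
        keep = [c for c in ("x_um", "y_um", "l_cell_um", "gamma") if c in extra.columns]
        meta = pd.concat([meta, extra[keep]], axis=1)
    frame_cols = pd.DataFrame(
        traces.intensities,
        columns=[f"{_TIME_PREFIX}{t:.3f}" for t in traces.time_s],
    )
    pd.concat([meta, frame_cols], axis=1).to_csv(path, index=False)


def read_traces_csv(path) -> tuple[TraceSet, pd.DataFrame]:
    """Read a wide trace CSV back into a TraceSet plus a metadata table."""
    df = pd.read_csv(path)
    time_cols = [c for c in df.columns if c.startswith(_TIME_PREFIX)]
    if not time_cols:
        raise ValueError(f"{path}: no t_<seconds> trace columns found")
    time_s = np.array([float(c[len(_TIME_PREFIX):]) for c in time_cols])
    order = np.argsort(time_s)
    traces = TraceSet(
        time_s=time_s[order],
        intensities=df[time_cols].to_numpy(dtype=float)[:, order],
        cell_ids=df["cell_id"].to_numpy(),
    )
    meta = df[[c for c in df.columns if not c.startswith(_TIME_PREFIX)]]
    return traces, meta


def write_truth_csv(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False)


def write_stack(path, stack: ImageStack, dt_s: float | None = None,
                delay_s: float | None = None, R_max_um: float | None = None,
                center_um: tuple[float, float] | None = None) -> None:
    """Write a stack as multi-page uint16 TIFF with a JSON sidecar.

    The brightfield companion goes next to it as ``<stem>_brightfield.tif``
    and the label mask as ``<stem>_labels.tif``.
    """
    path = Path(path)
    data = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {"pixel_size_um": stack.pixel_size_um}
    for key, val in (("dt_s", dt_s), ("delay_s", delay_s), ("R_max_um", R_max_um)):
        if val is not None:
            sidecar[key] = val
    if center_um is not None:
        sidecar["center_um"] = list(center_um)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if stack.brightfield is not None:
        tifffile.imwrite(
            path.with_name(path.stem + "_brightfield.tif"),
            np.clip(np.round(stack.brightfield), 0, 65535).astype(np.uint16),
        )
    if stack.labels is not None:
        write_labels(path.with_name(path.stem + "_labels.tif"), stack.labels)


def read_stack(path) -> tuple[ImageStack, dict]:
    """Read a TIFF stack plus sidecar; companions are picked up if present."""
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    brightfield_path = path.with_name(path.stem + "_brightfield.tif")
    labels_path = path.with_name(path.stem + "_labels.tif")
    stack = ImageStack(
        frames=frames,
        pixel_size_um=float(sidecar.get("pixel_size_um", 1.0)),
        brightfield=tifffile.imread(brightfield_path).astype(float) if brightfield_path.exists() else None,
        labels=read_labels(labels_path) if labels_path.exists() else None,
    )
    return stack, sidecar


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)
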