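"""Image-stack quantification: registration, background, beads, ROI traces.

Mirrors the quantification applied to the real time-lapse stacks:

1. align every frame to the final frame (translation only) to remove passive
   sample drift;
2. subtract the first frame from all subsequent frames to remove background;
3. exclude autofluorescent magnetic beads — circular objects larger than
   5 µm² and brighter than 15,000 AU;
4. measure each cell ROI (from a brightfield-derived labeled mask) across
   the whole stack;
5. convert positions to the normalised distance γ = l_cell / R_max from the
   cavitation center and keep cells with γ ≤ 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.registration import phase_cross_correlation

from .synthetic import ImageStack

__all__ = [
    "BeadMask",
    "register_stack",
    "subtract_background",
    "mask_beads",
    "extract_cell_traces",
    "compute_gamma",
    "filter_region",
    "DEFAULT_BEAD_AREA_MIN_UM2",
    "DEFAULT_BEAD_INTENSITY_MIN_AU",
    "DEFAULT_MAX_SHIFT_PX",
]

logger = logging.getLogger(__name__)

DEFAULT_BEAD_AREA_MIN_UM2 = 5.0
DEFAULT_BEAD_INTENSITY_MIN_AU = 15_000.0
DEFAULT_MAX_SHIFT_PX = 10.0


@dataclass
class BeadMask:
    """Pixels excluded as autofluorescent beads.

    Every excluded connected component passed both thresholds: area above
    ``area_min`` (µm²) *and* peak intensity above ``intensity_min`` (AU).
    """

    mask: np.ndarray  # (H, W) bool, True = excluded
    components: pd.DataFrame  # columns: label, area_um2, peak_intensity

    @property
    def n_components(self) -> int:
        return int(len(self.components))


def register_stack(stack: ImageStack, max_shift: float = DEFAULT_MAX_SHIFT_PX,
                   subpixel: bool = False) -> tuple[ImageStack, np.ndarray]:
    """Translate every frame onto the final frame by cross-correlation.

    Returns the registered stack and the applied (row, col) shift per frame.
    Shifts are integer-pixel by default and capped at ``max_shift`` pixels;
    a frame without content (zero variance) is passed through with zero
    shift and a warning.
    """
    frames = stack.frames
    if frames.shape[0] < 2:
        raise ValueError("registration needs at least 2 frames")
    reference = frames[-1]
    if reference.std() == 0:
        logger.warning("reference (final) frame has no content; registration skipped")
        return stack, np.zeros((frames.shape[0], 2))

    upsample = 10 if subpixel else 1
    shifts = np.zeros((frames.shape[0], 2))
    out = frames.copy()
    for i in range(frames.shape[0] - 1):
        if frames[i].std() == 0:
            logger.warning("frame %d has no content; registered with zero shift", i)
            continue
        shift, _, _ = phase_cross_correlation(reference, frames[i], upsample_factor=upsample)
        clipped = np.clip(shift, -max_shift, max_shift)
        if np.any(clipped != shift):
            logger.warning("frame %d shift %s capped at %s px", i, shift, max_shift)
        shifts[i] = clipped
        if np.any(clipped):
            order = 1 if subpixel else 0
            out[i] = ndi.shift(frames[i], clipped, order=order, mode="constant", cval=0.0)
    registered = ImageStack(
        frames=out,
        pixel_size_um=stack.pixel_size_um,
        brightfield=stack.brightfield,
        labels=stack.labels,
    )
    return registered, shifts


def subtract_background(stack: ImageStack) -> ImageStack:
    """Subtract the first frame from every frame, clipping at zero."""
    if stack.frames.shape[0] < 2:
        raise ValueError("background subtraction needs at least 2 frames")
    out = np.maximum(stack.frames - stack.frames[0], 0.0)
    return ImageStack(
        frames=out,
        pixel_size_um=stack.pixel_size_um,
        brightfield=stack.brightfield,
        labels=stack.labels,
    )


def mask_beads(
    frame: np.ndarray,
    area_min: float = DEFAULT_BEAD_AREA_MIN_UM2,
    intensity_min: float = DEFAULT_BEAD_INTENSITY_MIN_AU,
    pixel_size: float = 1.0,
) -> BeadMask:
    """Find autofluorescent beads on a single (unsubtracted) frame.

    A connected component is excluded only if it passes *both* thresholds:
    its pixels exceed ``intensity_min`` (AU) and its area exceeds
    ``area_min`` (µm²).  Bright-but-small and large-but-dim objects are kept.
    """
    if area_min <= 0 or intensity_min <= 0:
        raise ValueError("thresholds must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    bright = frame > intensity_min
    labeled = cc_label(bright, connectivity=2)
    mask = np.zeros(frame.shape, dtype=bool)
    rows = []
    px_area = pixel_size**2
    for prop in regionprops(labeled, intensity_image=frame):
        area_um2 = prop.area * px_area
        if area_um2 > area_min:
            mask[labeled == prop.label] = True
            rows.append(
                {
                    "label": prop.label,
                    "area_um2": area_um2,
                    "peak_intensity": float(prop.intensity_max),
                }
            )
    components = pd.DataFrame(rows, columns=["label", "area_um2", "peak_intensity"])
    return BeadMask(mask=mask, components=components)


def extract_cell_traces(
    stack: ImageStack,
    cell_mask: np.ndarray | None = None,
    bead_mask: BeadMask | None = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Measure every labeled cell ROI across the stack.

    Parameters
    ----------
    stack : registered, background-handled fluorescence stack.
    cell_mask : labeled 2-d integer mask (0 = background); defaults to the
        stack's own label image when it carries one.
    bead_mask : pixels to exclude from every ROI.
    statistic : ``"mean"`` (default, matching per-ROI mean intensity in AU)
        or ``"sum"``.

    Returns a wide table: cell_id, x_um, y_um, then one column per frame
    index holding the ROI statistic.  Positions are intensity-weighted
    centroids (weights from the final frame, geometric fallback) at pixel
    centers, in µm.  ROIs that fall entirely inside the bead mask are
    dropped and logged.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    if cell_mask is None:
        cell_mask = stack.labels
    if cell_mask is None:
        raise ValueError("no cell mask supplied and the stack carries none")
    cell_mask = np.asarray(cell_mask)
    if cell_mask.shape != stack.frames.shape[1:]:
        raise ValueError("cell mask shape does not match the frames")

    excluded = bead_mask.mask if bead_mask is not None else np.zeros(cell_mask.shape, bool)
    px = stack.pixel_size_um
    final = stack.frames[-1]
    rows = []
    traces = []
    for lbl in np.unique(cell_mask):
        if lbl == 0:
            continue
        roi = (cell_mask == lbl) & ~excluded
        if not np.any(roi):
            logger.warning("cell %d lies entirely inside the bead mask; dropped", lbl)
            continue
        rr, cc = np.nonzero(roi)
        weights = final[rr, cc]
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        cy = float(np.average(rr, weights=weights))
        cx = float(np.average(cc, weights=weights))
        vals = stack.frames[:, rr, cc]
        trace = vals.mean(axis=1) if statistic == "mean" else vals.sum(axis=1)
        rows.append({"cell_id": int(lbl), "x_um": (cx + 0.5) * px, "y_um": (cy + 0.5) * px})
        traces.append(trace)

    records = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um"])
    if traces:
        trace_df = pd.DataFrame(np.vstack(traces), columns=range(stack.n_frames))
        records = pd.concat([records, trace_df], axis=1)
    return records


def compute_gamma(
    records: pd.DataFrame,
    center: tuple[float, float],
    R_max: float,
) -> pd.DataFrame:
    """Attach l_cell = |r - center| (µm) and γ = l_cell / R_max to records."""
    if R_max <= 0:
        raise ValueError("R_max must be positive")
    out = records.copy()
    l_cell = np.hypot(out["x_um"] - center[0], out["y_um"] - center[1])
    out.insert(3, "l_cell_um", l_cell)
    out.insert(4, "gamma", l_cell / R_max)
    return out


def filter_region(records: pd.DataFrame, gamma_max: float = 3.0) -> pd.DataFrame:
    """Keep cells within γ ≤ gamma_max of the cavitation center (inclusive)."""
    if gamma_max < 0:
        raise ValueError("gamma_max must be nonnegative")
    if "gamma" not in records.columns:
        raise ValueError("records carry no gamma column; run compute_gamma first")
    return records[records["gamma"] <= gamma_max].reset_index(drop=True)
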