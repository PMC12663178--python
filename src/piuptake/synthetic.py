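"""Synthetic single-bubble cavitation experiments.

The real experiment images a lawn of surface-attached *E. coli* (density
0.28 cells/µm²) around a single collapsing microbubble (maximum radius
29.7 µm) and follows propidium-iodide uptake at 0.5 s intervals for 1300
frames, starting ~3 s after the collapse.  No raw stacks are deposited, so
this module generates fields with the same statistical structure: uniform
cell positions, a plateau-intensity law I_final(γ) = a + b/γ anchored at the
field center, per-cell first-order rate constants k ~ Normal(mean, sd)
truncated at a positive floor, saturating traces with additive Gaussian
noise, and (optionally) a rendered image stack with autofluorescent beads so
the extraction stage can be exercised end to end.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk, polygon

from .kinetics import RadialIntensityLaw

__all__ = [
    "CellField",
    "TraceSet",
    "ImageStack",
    "generate_cell_field",
    "assign_ground_truth",
    "simulate_traces",
    "render_stack",
    "DEFAULT_DENSITY",
    "DEFAULT_FOV_UM",
    "DEFAULT_R_MAX_UM",
    "DEFAULT_K_MEAN",
    "DEFAULT_K_SD",
    "DEFAULT_LAW",
]

# Study conditions: printed experimental parameters used as defaults.
DEFAULT_DENSITY = 0.28  # cells/µm² on the cover glass
DEFAULT_FOV_UM = 223.5  # field of view edge, µm (1024 px)
DEFAULT_R_MAX_UM = 29.7  # maximum bubble radius, µm
DEFAULT_K_MEAN = 0.0046  # 1/s, cohort mean uptake constant
DEFAULT_K_SD = 0.0018  # 1/s, cohort spread
DEFAULT_DT_S = 0.5  # frame interval
DEFAULT_N_FRAMES = 1300
DEFAULT_DELAY_S = 3.0  # mirror-switch delay between collapse and first frame
DEFAULT_NOISE_SD = 20.0  # AU, additive measurement noise on ROI intensity
DEFAULT_BEAD_RADIUS_UM = 1.5  # 3 µm magnetic beads
DEFAULT_BEAD_INTENSITY = 20_000.0  # AU, autofluorescence above the 15,000 AU mask threshold
K_FLOOR = 1e-5  # 1/s, truncation floor for the rate draw

DEFAULT_LAW = RadialIntensityLaw.from_coefficients(321.0, 228.0)


@dataclass
class CellField:
    """Cell and bead positions in a square field of view (µm coordinates)."""

    positions: np.ndarray  # (n_cells, 2) µm
    fov_size: float  # µm
    density: float  # cells/µm²
    bead_positions: np.ndarray  # (n_beads, 2) µm; first bead is the nucleation bead
    bead_radius: float  # µm
    seed: int

    @property
    def center(self) -> tuple[float, float]:
        """The cavitation center: the middle of the field of view."""
        return (self.fov_size / 2.0, self.fov_size / 2.0)

    @property
    def n_cells(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class TraceSet:
    """Per-cell fluorescence traces on a shared time axis.

    ``time_s`` is measured from the cavitation event; the first frame sits at
    the acquisition delay.
    """

    time_s: np.ndarray  # (n_frames,)
    intensities: np.ndarray  # (n_cells, n_frames), AU
    cell_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.intensities.shape[0])
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.intensities.shape != (len(self.cell_ids), len(self.time_s)):
            raise ValueError("intensities must be (n_cells, n_frames)")

    @property
    def n_cells(self) -> int:
        return int(self.intensities.shape[0])


@dataclass
class ImageStack:
    """A rendered fluorescence time-lapse plus segmentation companions."""

    frames: np.ndarray  # (n_frames, H, W), AU
    pixel_size_um: float
    brightfield: np.ndarray | None = None  # (H, W)
    labels: np.ndarray | None = None  # (H, W) int cell labels (0 = background)

    def __post_init__(self):
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def generate_cell_field(
    density: float = DEFAULT_DENSITY,
    fov_size: float = DEFAULT_FOV_UM,
    n_beads: int = 5,
    seed: int = 0,
    bead_radius: float = DEFAULT_BEAD_RADIUS_UM,
) -> CellField:
    """Draw a uniform cell field with autofluorescent beads.

    The cell count is Poisson(density × fov_size²) and positions are uniform
    on the square, matching the even lawn seen in brightfield before the
    collapse.  One bead (the nucleation bead) is always placed at the field
    center; the remainder are uniform.
    """
    if density < 0:
        raise ValueError("density must be nonnegative")
    if fov_size <= 0:
        raise ValueError("fov_size must be positive")
    if n_beads < 1:
        raise ValueError("need at least the nucleation bead")
    rng = np.random.default_rng(seed)
    n_cells = rng.poisson(density * fov_size**2)
    positions = rng.uniform(0.0, fov_size, size=(n_cells, 2))
    beads = rng.uniform(0.0, fov_size, size=(n_beads, 2))
    beads[0] = (fov_size / 2.0, fov_size / 2.0)
    return CellField(
        positions=positions,
        fov_size=float(fov_size),
        density=float(density),
        bead_positions=beads,
        bead_radius=float(bead_radius),
        seed=int(seed),
    )


def assign_ground_truth(
    cell_field: CellField,
    law: RadialIntensityLaw = DEFAULT_LAW,
    k_mean: float = DEFAULT_K_MEAN,
    k_sd: float = DEFAULT_K_SD,
    R_max: float = DEFAULT_R_MAX_UM,
    seed: int = 0,
    gamma_min: float = 0.05,
    detach_gamma: float | None = None,
) -> pd.DataFrame:
    """Ground-truth uptake parameters for every cell in a field.

    γ is the distance to the field center divided by ``R_max``; cells
    numerically at the center are clamped to ``gamma_min`` (the closest cells
    analysed in practice sit at γ ≈ 0.14).  The plateau is the radial law
    evaluated at γ, noise-free; per-cell rate constants are drawn
    Normal(k_mean, k_sd) with redraws below a small positive floor.

    ``detach_gamma`` optionally removes cells with γ < detach_gamma,
    emulating the annulus of detached cells seen around the collapse site.

    Returns a table with columns cell_id, x_um, y_um, gamma, I_final_true,
    k_true.
    """
    if k_mean <= 0:
        raise ValueError("k_mean must be positive")
    if k_sd < 0:
        raise ValueError("k_sd must be nonnegative")
    if R_max <= 0:
        raise ValueError("R_max must be positive")
    rng = np.random.default_rng(seed)
    cx, cy = cell_field.center
    dx = cell_field.positions[:, 0] - cx
    dy = cell_field.positions[:, 1] - cy
    gamma = np.hypot(dx, dy) / R_max
    gamma = np.maximum(gamma, gamma_min)

    n = gamma.size
    k_true = rng.normal(k_mean, k_sd, size=n)
    if k_sd > 0:
        for _ in range(1000):
            low = k_true < K_FLOOR
            if not np.any(low):
                break
            k_true[low] = rng.normal(k_mean, k_sd, size=int(low.sum()))
        k_true = np.maximum(k_true, K_FLOOR)
    i_final = law.predict(gamma) if n else np.empty(0)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": cell_field.positions[:, 0],
            "y_um": cell_field.positions[:, 1],
            "gamma": gamma,
            "I_final_true": i_final,
            "k_true": k_true,
        }
    )
    if detach_gamma is not None:
        truth = truth[truth["gamma"] >= detach_gamma].reset_index(drop=True)
    return truth


def simulate_traces(
    truth: pd.DataFrame,
    dt: float = DEFAULT_DT_S,
    n_frames: int = DEFAULT_N_FRAMES,
    delay: float = DEFAULT_DELAY_S,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> TraceSet:
    """Saturating uptake traces I(t) = I_final (1 - exp(-k t)) + noise.

    Time is measured from the cavitation event; the first frame is acquired
    at ``delay`` seconds.  Gaussian measurement noise of standard deviation
    ``noise_sd`` (AU) is added per frame and the result floored at zero, as a
    camera would never report negative background-subtracted counts.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    time_s = delay + dt * np.arange(n_frames)
    i_final = truth["I_final_true"].to_numpy(dtype=float)[:, None]
    k = truth["k_true"].to_numpy(dtype=float)[:, None]
    clean = i_final * (1.0 - np.exp(-k * time_s[None, :]))
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return TraceSet(
        time_s=time_s,
        intensities=np.maximum(clean, 0.0),
        cell_ids=truth["cell_id"].to_numpy(),
    )


def _rod_footprint(x_px: float, y_px: float, angle: float, length_px: float,
                   width_px: float, shape: tuple[int, int]):
    """Pixel indices of a rotated rectangular rod centred at (x, y)."""
    ux, uy = np.cos(angle), np.sin(angle)
    # perpendicular
    px_, py_ = -uy, ux
    hl, hw = length_px / 2.0, width_px / 2.0
    corners_x = np.array([x_px + sx * hl * ux + sw * hw * px_
                          for sx, sw in ((1, 1), (1, -1), (-1, -1), (-1, 1))])
    corners_y = np.array([y_px + sx * hl * uy + sw * hw * py_
                          for sx, sw in ((1, 1), (1, -1), (-1, -1), (-1, 1))])
    rr, cc = polygon(corners_y, corners_x, shape=shape)
    return rr, cc


def render_stack(
    cell_field: CellField,
    traces: TraceSet,
    pixel_size: float,
    bead_intensity: float = DEFAULT_BEAD_INTENSITY,
    seed: int = 0,
    cell_length_um: float = 2.0,
    cell_width_um: float = 1.0,
) -> ImageStack:
    """Rasterise a trace set into a fluorescence image stack.

    Each cell is painted as a rod (2 × 1 µm rectangle, random orientation)
    whose pixels all carry the cell's trace value for that frame, so the ROI
    *mean* over the footprint reproduces the trace exactly up to overlap.
    Overlapping footprints are summed.  Beads are painted as discs of
    constant ``bead_intensity`` in every frame (they autofluoresce
    throughout).  The companion brightfield frame marks all cell footprints,
    and ``labels`` holds a per-cell integer mask for ROI extraction.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    n_px = int(round(cell_field.fov_size / pixel_size))
    shape = (n_px, n_px)
    n_frames = len(traces.time_s)
    rng = np.random.default_rng(seed)

    frames = np.zeros((n_frames,) + shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    brightfield = np.full(shape, 100.0)

    if cell_field.n_cells != traces.n_cells:
        raise ValueError("field and traces disagree on the number of cells")

    footprints = []
    for i in range(cell_field.n_cells):
        x_um, y_um = cell_field.positions[i]
        angle = rng.uniform(0.0, np.pi)
        rr, cc = _rod_footprint(
            x_um / pixel_size,
            y_um / pixel_size,
            angle,
            cell_length_um / pixel_size,
            cell_width_um / pixel_size,
            shape,
        )
        footprints.append((rr, cc))
        labels[rr, cc] = i + 1
        brightfield[rr, cc] = 500.0

    for f in range(n_frames):
        frame = frames[f]
        for i, (rr, cc) in enumerate(footprints):
            frame[rr, cc] += traces.intensities[i, f]

    for bx, by in cell_field.bead_positions:
        rr, cc = disk(
            (by / pixel_size, bx / pixel_size),
            cell_field.bead_radius / pixel_size,
            shape=shape,
        )
        frames[:, rr, cc] += bead_intensity
        brightfield[rr, cc] = 800.0

    return ImageStack(
        frames=frames,
        pixel_size_um=float(pixel_size),
        brightfield=brightfield,
        labels=labels,
    )
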