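"""End-to-end orchestration: data in, traces, fits, model fields, figures.

Three entry modes share the downstream stages:

* ``synthetic`` — generate a cell field, ground truth and noisy traces;
* ``stack`` — quantify a supplied TIFF stack with a labeled cell mask;
* ``traces`` — start from a per-cell trace CSV.

Every run writes into a run directory: the resolved configuration, trace
and fit tables, a population summary, the Goldman field maps, and (by
default) publication-style figures.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import extraction, io, synthetic
from .config import PipelineConfig
from .goldman import FieldMap, build_field_map
from .kinetics import (
    RadialIntensityLaw,
    fit_traces,
    initial_rate_vs_final,
    population_k_stats,
)

__all__ = ["run_pipeline", "export_field_maps", "simulate_cohort"]

logger = logging.getLogger(__name__)


def simulate_cohort(config: PipelineConfig, n_cells: int | None = None,
                    seed: int | None = None):
    """Generate a γ ≤ gamma_max cohort of ground truth plus noisy traces.

    Draws the full field at the configured density, restricts to the
    analysis region, optionally subsamples to ``n_cells`` without
    replacement, and simulates the traces.  Returns (truth, traces).
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_field, s_truth, s_sub, s_noise = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    field = synthetic.generate_cell_field(
        density=config.density_per_um2,
        fov_size=config.fov_um,
        n_beads=config.n_beads,
        seed=s_field,
        bead_radius=config.bead_radius_um,
    )
    truth = synthetic.assign_ground_truth(
        field,
        law=config.law(),
        k_mean=config.k_mean,
        k_sd=config.k_sd,
        R_max=config.R_max_um,
        seed=s_truth,
        gamma_min=config.gamma_min,
        detach_gamma=config.detach_gamma,
    )
    truth = truth[truth["gamma"] <= config.gamma_max].reset_index(drop=True)
    if n_cells is not None and len(truth) > n_cells:
        rng = np.random.default_rng(s_sub)
        pick = np.sort(rng.choice(len(truth), size=n_cells, replace=False))
        truth = truth.iloc[pick].reset_index(drop=True)
    traces = synthetic.simulate_traces(
        truth,
        dt=config.dt_s,
        n_frames=config.n_frames,
        delay=config.delay_s,
        noise_sd=config.noise_sd_au,
        seed=s_noise,
    )
    return truth, traces


def _extract_stage(config: PipelineConfig):
    stack, sidecar = io.read_stack(config.stack_path)
    if config.mask_path is not None:
        cell_mask = io.read_labels(config.mask_path)
    else:
        cell_mask = stack.labels
    if cell_mask is None:
        raise ValueError("stack mode needs a labeled cell mask (mask_path or companion TIFF)")
    registered, _ = extraction.register_stack(stack, max_shift=config.max_shift_px)
    bead = extraction.mask_beads(
        registered.frames[0],
        area_min=config.bead_area_min_um2,
        intensity_min=config.bead_intensity_min_au,
        pixel_size=registered.pixel_size_um,
    )
    subtracted = extraction.subtract_background(registered)
    records = extraction.extract_cell_traces(subtracted, cell_mask, bead, statistic=config.roi_statistic)
    center = tuple(sidecar.get("center_um", (config.fov_um / 2, config.fov_um / 2)))
    r_max = float(sidecar.get("R_max_um", config.R_max_um))
    records = extraction.compute_gamma(records, center, r_max)
    records = extraction.filter_region(records, config.gamma_max)
    dt = float(sidecar.get("dt_s", config.dt_s))
    delay = float(sidecar.get("delay_s", config.delay_s))
    frame_cols = [c for c in records.columns if isinstance(c, (int, np.integer))]
    traces = synthetic.TraceSet(
        time_s=delay + dt * np.array(frame_cols, dtype=float),
        intensities=records[frame_cols].to_numpy(dtype=float),
        cell_ids=records["cell_id"].to_numpy(),
    )
    meta = records[["cell_id", "x_um", "y_um", "l_cell_um", "gamma"]]
    return traces, meta


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the staged pipeline for the configured mode.

    Returns the run directory, which afterwards contains ``config.yaml``,
    ``traces.csv``, ``fits.csv``, ``summary.json``, ``fields.csv`` and the
    figures (unless disabled).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    logger.info("run directory %s, mode %s, seed %d", out, config.mode, config.seed)

    truth = None
    if config.mode == "synthetic":
        truth, traces = simulate_cohort(config)
        io.write_truth_csv(out / "truth.csv", truth)
        meta = truth[["cell_id", "x_um", "y_um", "gamma"]]
    elif config.mode == "traces":
        if config.traces_path is None:
            raise ValueError("traces mode needs traces_path")
        traces, meta = io.read_traces_csv(config.traces_path)
    else:
        if config.stack_path is None:
            raise ValueError("stack mode needs stack_path")
        traces, meta = _extract_stage(config)
    io.write_traces_csv(out / "traces.csv", traces, meta)

    gamma = meta.set_index("cell_id").loc[traces.cell_ids, "gamma"].to_numpy() \
        if "gamma" in meta.columns else None
    fits = fit_traces(
        traces.intensities,
        traces.time_s,
        cell_ids=traces.cell_ids,
        gamma=gamma,
        initial_rate_guess=config.initial_rate_guess,
    )
    fits.to_csv(out / "fits.csv", index=False)

    stats = population_k_stats(fits, n_sigma=config.outlier_sigma)
    converged = fits[fits["converged"]]
    radial = None
    if gamma is not None and converged["gamma"].nunique() >= 2:
        radial = RadialIntensityLaw().fit(converged["gamma"], converged["I_final"])
    rate_fit = initial_rate_vs_final(fits)
    summary = {
        "n_cells": int(len(fits)),
        "n_converged": int(converged.shape[0]),
        "mean_k_per_s": stats.mean_k,
        "sd_k_per_s": stats.sd_k,
        "tau_char_s": stats.tau_char,
        "n_used": stats.n_used,
        "n_excluded_outliers": stats.n_excluded,
        "radial_intercept_au": None if radial is None else radial.intercept_,
        "radial_coef_au": None if radial is None else radial.coef_,
        "radial_r_squared": None if radial is None else radial.r_squared_,
        "initial_rate_slope_per_s": rate_fit.slope,
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    law = radial if radial is not None else config.law()
    gamma_grid = np.linspace(0.14, config.gamma_max, config.field_gamma_points)
    t_grid = np.linspace(0.0, config.T_obs_s, config.field_t_points)
    field_map = build_field_map(
        config.goldman_params(), stats.mean_k, law, gamma_grid, t_grid,
        solver=config.goldman_solver,
    )
    export_field_maps(field_map, out, make_figures=config.make_figures)

    if config.make_figures:
        _figures(out, fits, traces, stats, radial, truth)
    return out


def export_field_maps(fields: FieldMap, out_dir, make_figures: bool = True) -> list[Path]:
    """Write the field maps as long CSV plus 2-D images."""
    if fields.gamma.size == 0 or fields.t_s.size == 0:
        raise ValueError("field map grids are empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = [out / "fields.csv"]
    fields.to_dataframe().to_csv(written[0], index=False, float_format="%.10g")
    if make_figures:
        for name, arr, label in (
            ("field_I", fields.I, "I (AU)"),
            ("field_P_over_p0", fields.P_over_p0, "P/p0"),
            ("field_S_p", fields.S_p, "S_p"),
        ):
            fig, ax = plt.subplots(figsize=(5, 4))
            pcm = ax.pcolormesh(fields.t_s, fields.gamma, arr, shading="auto")
            ax.set_xlabel("t (s)")
            ax.set_ylabel(r"$\gamma$")
            fig.colorbar(pcm, ax=ax, label=label)
            path = out / f"{name}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written


def _figures(out: Path, fits: pd.DataFrame, traces, stats, radial, truth) -> None:
    converged = fits[fits["converged"]]

    if converged["gamma"].notna().any():
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(converged["gamma"], converged["I_final"], s=4, alpha=0.3, label="cells")
        if radial is not None:
            gg = np.linspace(max(converged["gamma"].min(), 0.05), converged["gamma"].max(), 200)
            ax.plot(gg, radial.predict(gg), color="green",
                    label=f"{radial.intercept_:.0f} + {radial.coef_:.0f}/$\\gamma$")
        ax.set_xlabel(r"$\gamma$")
        ax.set_ylabel(r"$I_{final}$ (AU)")
        ax.legend()
        fig.savefig(out / "radial_law.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(converged["k"], bins=50)
    ax.axvline(stats.mean_k, color="k", ls="--",
               label=f"mean {stats.mean_k:.4g} 1/s")
    ax.set_xlabel("k (1/s)")
    ax.set_ylabel("cells")
    ax.legend()
    fig.savefig(out / "k_histogram.png", dpi=120)
    plt.close(fig)

    # single-cell saturation example: the converged cell nearest the median plateau
    if len(converged):
        idx = (converged["I_final"] - converged["I_final"].median()).abs().idxmin()
        row = converged.loc[idx]
        pos = np.nonzero(traces.cell_ids == row["cell_id"])[0][0]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(traces.time_s, traces.intensities[pos], ".", ms=2, alpha=0.5, label="trace")
        ax.plot(traces.time_s, row["I_final"] * (1 - np.exp(-row["k"] * traces.time_s)),
                color="green", label=f"fit: k={row['k']:.4g} 1/s")
        ax.set_xlabel("t (s)")
        ax.set_ylabel("I (AU)")
        ax.legend()
        fig.savefig(out / "single_cell_fit.png", dpi=120)
        plt.close(fig)
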