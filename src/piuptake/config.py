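"""Pipeline configuration with the study's experimental defaults.

A single flat mapping covers every stage; unknown keys are rejected on load
so a typo in a YAML file fails loudly instead of silently keeping a default.
Each run writes its fully resolved configuration next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with experimental defaults."""

    mode: str = "synthetic"  # synthetic | stack | traces
    seed: int = 0

    # --- field / acquisition geometry ---
    density_per_um2: float = 0.28
    fov_um: float = 223.5
    image_px: int = 1024
    R_max_um: float = 29.7
    dt_s: float = 0.5
    n_frames: int = 1300
    delay_s: float = 3.0

    # --- ground-truth generator ---
    law_intercept_au: float = 321.0
    law_coef_au: float = 228.0
    k_mean: float = 0.0046
    k_sd: float = 0.0018
    noise_sd_au: float = 20.0
    gamma_min: float = 0.05
    detach_gamma: float | None = None
    n_beads: int = 5
    bead_radius_um: float = 1.5
    bead_intensity_au: float = 20000.0

    # --- extraction ---
    bead_area_min_um2: float = 5.0
    bead_intensity_min_au: float = 15000.0
    max_shift_px: float = 10.0
    roi_statistic: str = "mean"  # mean | sum
    gamma_max: float = 3.0

    # --- kinetics ---
    initial_rate_guess: float = 0.01
    outlier_sigma: float = 3.0

    # --- Goldman model (SI units) ---
    c0_mol_m3: float = 6e-5
    dPhi_m_V: float = 0.125
    z_valence: float = 2.0
    temperature_K: float = 300.0
    D_m2_s: float = 1e-12
    L_m: float = 50e-9
    h0_m: float = 2e-6
    a_cell_m: float = 2e-6
    r_e_m: float = 0.5e-6
    rho_m2: float = 0.275e12
    beta: float = 0.41
    T_obs_s: float = 600.0
    k1_m_per_au: float = 0.011
    I_100_au: float = 2500.0
    kappa_override_m: float | None = None
    phi_override: float | None = None
    field_gamma_points: int = 60
    field_t_points: int = 121
    goldman_solver: str = "analytic"  # analytic | numeric

    # --- io ---
    stack_path: str | None = None
    mask_path: str | None = None
    traces_path: str | None = None
    make_figures: bool = True

    @property
    def pixel_size_um(self) -> float:
        return self.fov_um / self.image_px

    def goldman_params(self):
        from .goldman import GoldmanParams

        return GoldmanParams(
            c0=self.c0_mol_m3,
            dPhi_m=self.dPhi_m_V,
            z=self.z_valence,
            T=self.temperature_K,
            D=self.D_m2_s,
            L=self.L_m,
            h0=self.h0_m,
            a_cell=self.a_cell_m,
            r_e=self.r_e_m,
            rho=self.rho_m2,
            beta=self.beta,
            R_max=self.R_max_um * 1e-6,
            T_obs=self.T_obs_s,
            k1=self.k1_m_per_au,
            I_100=self.I_100_au,
            kappa_override=self.kappa_override_m,
            phi_override=self.phi_override,
        )

    def law(self):
        from .kinetics import RadialIntensityLaw

        return RadialIntensityLaw.from_coefficients(self.law_intercept_au, self.law_coef_au)

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("synthetic", "stack", "traces"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.roi_statistic not in ("mean", "sum"):
            raise ValueError("roi_statistic must be 'mean' or 'sum'")
        if self.goldman_solver not in ("analytic", "numeric"):
            raise ValueError("goldman_solver must be 'analytic' or 'numeric'")
        for name in ("density_per_um2", "noise_sd_au"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("fov_um", "R_max_um", "dt_s", "k_mean", "gamma_max", "dt_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config (optional) and apply keyword overrides.

    Unknown keys, in the file or the overrides, raise ``ValueError``.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data).validate()
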