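"""Modified Goldman transport model for dye influx through transient pores.

The micrograph is modelled as a thin two-compartment system: dimensionless
dye concentration outside the cells (c1) and inside (c2), with c1 + c2 = 1
and c1(γ, 0) = 1.  Flux across the damaged membranes follows a Goldman-type
relation driven by the transmembrane potential, with a permeability field

    P(γ, t) = k1 ∂I/∂t = k k1 I_final(γ) e^{-k t}

that is maximal at the moment of collapse and decays as pores reseal.  In
dimensionless time t̃ = t / T_obs the outside concentration obeys

    dc1/dt̃ = α (P/p0)(γ, t̃) (c2 α_m - c1) / (1 - α_m),

with α = p0 T_obs φ / κ, φ = z e0 ΔΦ_m / (kB T) the dimensionless
transmembrane potential, α_m = exp(-φ), and κ the outside-volume to
cell-surface ratio of the chamber.  Because the potential term is large
(α_m ≈ 1e-4) the system integrates in closed form to

    c1(γ, t̃) = exp[(φ k1 / κ) I_final(γ) (e^{-θ t̃} - 1)],   θ = k T_obs,

whose first-order expansion in the small prefactor reproduces the measured
saturation time course — the basis for reading fluorescence as an intensity
proxy for internal concentration, I = c2 c0 k2 with k2 = κ/(φ k1 c0).

All computation is in SI units; fluorescence stays in camera AU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann as KB
from scipy.constants import elementary_charge as E0
from scipy.integrate import solve_ivp

from .kinetics import RadialIntensityLaw

__all__ = [
    "GoldmanParams",
    "DerivedConstants",
    "FieldMap",
    "derive_constants",
    "permeability_field",
    "damage_fraction",
    "solve_goldman_numeric",
    "solve_goldman_analytic",
    "c2_linearized",
    "calibrate_k2",
    "transmembrane_potential",
    "build_field_map",
]


@dataclass(frozen=True)
class GoldmanParams:
    """Physical and geometric constants of the chamber and dye.

    Units are SI throughout; ``k1`` converts an intensity rate to a
    permeability (m/AU) and ``I_100`` is the plateau intensity read as total
    membrane damage.
    """

    c0: float = 6e-5  # initial PI concentration, mol/m³ (60 nM)
    dPhi_m: float = 0.125  # transmembrane potential, V
    z: float = 2.0  # PI ion valence
    T: float = 300.0  # temperature, K
    D: float = 1e-12  # PI diffusion constant, m²/s
    L: float = 50e-9  # transmembrane pore path length, m
    h0: float = 2e-6  # chamber depth, m (one cell length)
    a_cell: float = 2e-6  # cell length, m
    r_e: float = 0.5e-6  # cell radius, m
    rho: float = 0.275e12  # planar cell density, 1/m²
    beta: float = 0.41  # cell volume fraction of the chamber
    R_max: float = 29.7e-6  # maximum bubble radius, m
    T_obs: float = 600.0  # observation window, s
    k1: float = 0.011  # permeability-intensity factor, m/AU
    I_100: float = 2500.0  # AU read as 100% membrane damage
    # Printed-scalar overrides for constants that the geometric/electrostatic
    # formulas do not reproduce; None means "compute from the formula".
    kappa_override: float | None = None
    phi_override: float | None = None

    def __post_init__(self):
        positive = ("c0", "dPhi_m", "z", "T", "D", "L", "h0", "a_cell",
                    "r_e", "rho", "R_max", "T_obs", "k1", "I_100")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")

    def with_overrides(self, **kwargs) -> "GoldmanParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedConstants:
    """Constants derived from :class:`GoldmanParams` and a rate constant k."""

    p0: float  # characteristic permeability D/L, m/s
    phi: float  # dimensionless transmembrane potential
    alpha_m: float  # exp(-phi)
    kappa: float  # outside volume / total cell surface, m
    alpha: float  # ODE scaling factor p0 T_obs phi / kappa
    theta: float  # dimensionless resealing constant k T_obs


def kappa_from_geometry(params: GoldmanParams) -> float:
    """V_out/(N_e A_e) for cylinder cells of length a and radius r_e at
    planar density rho: a r_e (1/(π r_e²) - ρ) / (2 ρ (r_e + a))."""
    a, r, rho = params.a_cell, params.r_e, params.rho
    return a * r * (1.0 / (np.pi * r**2) - rho) / (2.0 * rho * (r + a))


def derive_constants(params: GoldmanParams, k: float) -> DerivedConstants:
    """Evaluate p0, φ, α_m, κ, α and θ for a fitted uptake constant ``k``."""
    if k <= 0:
        raise ValueError("k must be positive")
    p0 = params.D / params.L
    if params.phi_override is not None:
        phi = params.phi_override
    else:
        phi = params.z * E0 * params.dPhi_m / (KB * params.T)
    kappa = params.kappa_override if params.kappa_override is not None else kappa_from_geometry(params)
    theta = k * params.T_obs
    alpha = p0 * params.T_obs * phi / kappa
    return DerivedConstants(
        p0=p0,
        phi=phi,
        alpha_m=float(np.exp(-phi)),
        kappa=kappa,
        alpha=alpha,
        theta=theta,
    )


def _check_gamma(gamma):
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("gamma must be strictly positive")
    return gamma


def _law_over(law: RadialIntensityLaw, gamma: np.ndarray) -> np.ndarray:
    """Evaluate the radial law elementwise on an arbitrarily shaped grid."""
    return np.asarray(law.predict(np.ravel(gamma))).reshape(np.shape(gamma))


def permeability_field(gamma, t, k: float, k1: float, law: RadialIntensityLaw):
    """Membrane permeability P(γ, t) = k k1 I_final(γ) e^{-k t} in m/s.

    Maximal at the collapse (t = 0) and decaying as pores reseal; ``t`` is in
    seconds.  Factorises exactly into a spatial and a temporal part.
    """
    gamma = _check_gamma(gamma)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return k * k1 * _law_over(law, gamma) * np.exp(-k * t)


def damage_fraction(gamma, t, k: float, k1: float, law: RadialIntensityLaw,
                    p0: float, I_100: float = 2500.0, raw: bool = False):
    """Pore area fraction S_p(γ, t) of the cell membrane.

    The raw Goldman estimate is S_p = (k k1 / p0) I_final(γ) e^{-k t}
    (identical to the relative permeability P/p0, since the pore density n
    and pore radius r_p enter only through n π r_p² = P/p0).  With the
    printed constants this exceeds one, so the reported fraction is
    normalised such that a plateau of ``I_100`` AU at t = 0 maps to S_p = 1
    — the calibration that reads 2500 AU as a totally damaged cell — and is
    then capped to [0, 1].  Pass ``raw=True`` for the unnormalised value.
    """
    gamma = _check_gamma(gamma)
    t = np.asarray(t, dtype=float)
    value = (k * k1 / p0) * _law_over(law, gamma) * np.exp(-k * t)
    if raw:
        return value
    reference = (k * k1 / p0) * I_100  # raw value of a totally damaged cell at t = 0
    return np.clip(value / reference, 0.0, 1.0)


def solve_goldman_analytic(gamma, t_dimless, consts: DerivedConstants,
                           law: RadialIntensityLaw, k1: float):
    """Closed-form c1, c2 on a γ × t̃ grid (t̃ = t / T_obs).

    c1 = exp[(φ k1/κ) I_final(γ) (e^{-θ t̃} - 1)];  c2 = 1 - c1.
    Broadcasting: returns arrays of shape (len(gamma), len(t)).
    """
    gamma = np.atleast_1d(_check_gamma(gamma))
    t = np.atleast_1d(np.asarray(t_dimless, dtype=float))
    if np.any(t < 0):
        raise ValueError("dimensionless time must be nonnegative")
    prefactor = consts.phi * k1 / consts.kappa
    exponent = prefactor * law.predict(gamma)[:, None] * (np.exp(-consts.theta * t)[None, :] - 1.0)
    c1 = np.exp(exponent)
    return c1, 1.0 - c1


def c2_linearized(gamma, t_dimless, consts: DerivedConstants,
                  law: RadialIntensityLaw, k1: float, validity_threshold: float = 0.1):
    """First-order (small prefactor) internal concentration.

    c2 ≈ (φ k1/κ) I_final(γ) (1 - e^{-θ t̃}) — the same time course as the
    measured saturation curve, which is what licenses reading fluorescence
    as concentration.  Warns when the expansion parameter exceeds
    ``validity_threshold``.
    """
    gamma = np.atleast_1d(_check_gamma(gamma))
    t = np.atleast_1d(np.asarray(t_dimless, dtype=float))
    prefactor = consts.phi * k1 / consts.kappa
    magnitude = float(np.max(np.abs(prefactor * law.predict(gamma))))
    if magnitude > validity_threshold:
        warnings.warn(
            f"linearization parameter {magnitude:.3g} exceeds {validity_threshold}; "
            "the first-order expansion is inaccurate here",
            RuntimeWarning,
            stacklevel=2,
        )
    return prefactor * law.predict(gamma)[:, None] * (1.0 - np.exp(-consts.theta * t)[None, :])


@dataclass
class FieldMap:
    """Gridded spatiotemporal fields around the cavitation center."""

    gamma: np.ndarray  # (G,)
    t_s: np.ndarray  # (T,) seconds
    I: np.ndarray  # (G, T) fluorescence, AU
    P_over_p0: np.ndarray  # (G, T) relative permeability
    S_p: np.ndarray  # (G, T) damage fraction in [0, 1]
    c1: np.ndarray  # (G, T) outside concentration
    c2: np.ndarray  # (G, T) inside concentration

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: gamma, t_s, I, P_over_p0, S_p, c1, c2."""
        gg, tt = np.meshgrid(self.gamma, self.t_s, indexing="ij")
        return pd.DataFrame(
            {
                "gamma": gg.ravel(),
                "t_s": tt.ravel(),
                "I": self.I.ravel(),
                "P_over_p0": self.P_over_p0.ravel(),
                "S_p": self.S_p.ravel(),
                "c1": self.c1.ravel(),
                "c2": self.c2.ravel(),
            }
        )


def solve_goldman_numeric(
    params: GoldmanParams,
    consts: DerivedConstants,
    law: RadialIntensityLaw,
    k1: float,
    gamma_grid,
    t_grid_s,
    continuity: str = "conservation",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the two-compartment Goldman system on a γ × t grid.

    ``t_grid_s`` is in seconds; integration runs in dimensionless time
    t̃ = t / T_obs.  Each radius evolves independently (radial symmetry), so
    all γ are integrated as one decoupled vector ODE.

    continuity
        ``"conservation"`` (default): c2 = 1 - c1 is substituted into the
        Goldman flux term, honouring the normalisation c1 + c2 = 1 exactly —
        the closure under which the analytic solution is derived.
        ``"volume_fraction"``: the inside compartment instead follows
        dc2/dt̃ = ((β - 1)/β) dc1/dt̃; with β ≠ 1/2 this bookkeeping does not
        conserve c1 + c2 and is provided for comparison only.

    Returns (c1, c2) of shape (len(gamma), len(t)).
    """
    if continuity not in ("conservation", "volume_fraction"):
        raise ValueError("continuity must be 'conservation' or 'volume_fraction'")
    gamma = np.atleast_1d(_check_gamma(gamma_grid))
    t_s = np.atleast_1d(np.asarray(t_grid_s, dtype=float))
    if gamma.size == 0 or t_s.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any(t_s < 0):
        raise ValueError("t must be nonnegative")
    t_tilde = t_s / params.T_obs

    # alpha * (P/p0) = A(gamma) * exp(-theta * t̃) with
    # A = alpha * (k k1 / p0) I_final; note alpha k k1 / (p0 theta) = phi k1 / kappa.
    k = consts.theta / params.T_obs
    amp = consts.alpha * (k * k1 / consts.p0) * law.predict(gamma)
    am = consts.alpha_m
    theta = consts.theta

    if continuity == "conservation":
        def rhs(t, c1):
            drive = amp * np.exp(-theta * t)
            return -drive * (c1 - (1.0 - c1) * am) / (1.0 - am)

        def jac(t, c1):
            drive = amp * np.exp(-theta * t)
            return np.diag(-drive * (1.0 + am) / (1.0 - am))

        y0 = np.ones(gamma.size)
    else:
        n = gamma.size

        def rhs(t, y):
            c1, c2 = y[:n], y[n:]
            drive = amp * np.exp(-theta * t)
            dc1 = drive * (c2 * am - c1) / (1.0 - am)
            dc2 = ((params.beta - 1.0) / params.beta) * dc1
            return np.concatenate([dc1, dc2])

        jac = None
        y0 = np.concatenate([np.ones(n), np.zeros(n)])

    # solve_ivp needs a strictly positive span; prepend t=0 if absent.
    t_eval = t_tilde
    prepend = t_eval[0] > 0.0
    if prepend:
        t_eval = np.concatenate([[0.0], t_eval])
    if t_eval.size == 1:  # a single requested time at t=0
        c1 = np.ones((gamma.size, 1))
        return c1, 1.0 - c1

    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=jac if continuity == "conservation" else None,
    )
    if not sol.success:
        raise RuntimeError(f"Goldman ODE integration failed: {sol.message}")
    y = sol.y[:, 1:] if prepend else sol.y
    if continuity == "conservation":
        c1 = y
        c2 = 1.0 - c1
    else:
        c1, c2 = y[: gamma.size], y[gamma.size:]
    return c1, c2


def calibrate_k2(params: GoldmanParams, consts: DerivedConstants, k1: float | None = None) -> float:
    """Intensity-per-concentration factor k2 = κ / (φ k1 c0), AU·m³/mol.

    Defined so that the linearised internal concentration reproduces the
    measured intensity via I = c2 c0 k2, i.e. φ k1 k2 c0 / κ = 1.
    """
    k1 = params.k1 if k1 is None else k1
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    return consts.kappa / (consts.phi * k1 * params.c0)


def transmembrane_potential(params: GoldmanParams, k1: float, k2: float,
                            kappa: float | None = None) -> float:
    """Invert the intensity calibration into the membrane potential (V).

    ΔΦ_m = κ kB T / (z e0 c0 k1 k2), with κ = V_out/(N_e A_e).  Exact
    algebraic inverse of :func:`calibrate_k2` under φ = z e0 ΔΦ_m / (kB T).
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("k1 and k2 must be positive")
    if kappa is None:
        kappa = params.kappa_override if params.kappa_override is not None else kappa_from_geometry(params)
    return kappa * KB * params.T / (params.z * E0 * params.c0 * k1 * k2)


def build_field_map(
    params: GoldmanParams,
    k: float,
    law: RadialIntensityLaw,
    gamma_grid,
    t_grid_s,
    solver: str = "analytic",
) -> FieldMap:
    """Evaluate all spatiotemporal fields on a γ × t grid.

    I(γ, t) from the saturation law, P/p0 and S_p from the permeability
    field, and c1/c2 from the Goldman model (closed form by default,
    ``solver="numeric"`` for the ODE integration).
    """
    gamma = np.atleast_1d(_check_gamma(gamma_grid))
    t_s = np.atleast_1d(np.asarray(t_grid_s, dtype=float))
    if gamma.size == 0 or t_s.size == 0:
        raise ValueError("grids must be nonempty")
    consts = derive_constants(params, k)
    i_final = law.predict(gamma)[:, None]
    intensity = i_final * (1.0 - np.exp(-k * t_s)[None, :])
    p_rel = (k * params.k1 / consts.p0) * i_final * np.exp(-k * t_s)[None, :]
    s_p = damage_fraction(
        np.repeat(gamma[:, None], t_s.size, axis=1),
        np.repeat(t_s[None, :], gamma.size, axis=0),
        k, params.k1, law, consts.p0, params.I_100,
    )
    if solver == "analytic":
        c1, c2 = solve_goldman_analytic(gamma, t_s / params.T_obs, consts, law, params.k1)
    elif solver == "numeric":
        c1, c2 = solve_goldman_numeric(params, consts, law, params.k1, gamma, t_s)
    else:
        raise ValueError("solver must be 'analytic' or 'numeric'")
    return FieldMap(gamma=gamma, t_s=t_s, I=intensity, P_over_p0=p_rel,
                    S_p=s_p, c1=c1, c2=c2)
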