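"""Derived constants, permeability/damage fields, and the Goldman solvers."""

import dataclasses

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piuptake.goldman import (
    FieldMap,
    GoldmanParams,
    build_field_map,
    c2_linearized,
    calibrate_k2,
    damage_fraction,
    derive_constants,
    kappa_from_geometry,
    permeability_field,
    solve_goldman_analytic,
    solve_goldman_numeric,
    transmembrane_potential,
)
from piuptake.kinetics import RadialIntensityLaw

K_PAPER = 0.0046


@pytest.fixture(scope="module")
def params():
    return GoldmanParams()


@pytest.fixture(scope="module")
def consts(params):
    return derive_constants(params, K_PAPER)


class TestDerivedConstants:
    def test_characteristic_permeability(self, consts):
        # p0 = D / L = 1e-12 / 50e-9
        assert consts.p0 == pytest.approx(2e-5, rel=1e-12)

    def test_dimensionless_potential_from_formula(self, consts):
        # z e0 ΔΦ / (kB T) with z=2, ΔΦ=125 mV, T=300 K
        assert consts.phi == pytest.approx(9.670, rel=1e-3)
        assert consts.alpha_m == pytest.approx(np.exp(-consts.phi))

    def test_kappa_from_geometry(self, consts):
        # a r_e (1/(π r_e²) − ρ) / (2 ρ (r_e + a)) with printed cell geometry
        assert consts.kappa == pytest.approx(7.26e-7, rel=1e-2)

    def test_theta_and_alpha_definitions(self, params, consts):
        assert consts.theta == pytest.approx(K_PAPER * params.T_obs)
        assert consts.alpha == pytest.approx(
            consts.p0 * params.T_obs * consts.phi / consts.kappa
        )

    def test_overrides_take_precedence(self):
        p = GoldmanParams(kappa_override=8.68e5, phi_override=11.57)
        c = derive_constants(p, K_PAPER)
        assert c.kappa == 8.68e5 and c.phi == 11.57

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GoldmanParams(beta=1.5)
        with pytest.raises(ValueError):
            GoldmanParams(T=-1.0)


class TestPermeability:
    def test_value_at_bubble_radius_at_collapse(self, paper_law):
        # k k1 I_final(1) = 0.0046 · 0.011 · 549
        p = permeability_field(1.0, 0.0, K_PAPER, 0.011, paper_law)
        assert p == pytest.approx(0.0046 * 0.011 * 549.0, rel=1e-12)

    def test_decay_ratio_over_one_characteristic_time(self, paper_law):
        p0t = permeability_field(2.0, 0.0, K_PAPER, 0.011, paper_law)
        p1t = permeability_field(2.0, 1.0 / K_PAPER, K_PAPER, 0.011, paper_law)
        assert p0t / p1t == pytest.approx(np.e, rel=1e-12)

    def test_vanishes_at_long_times(self, paper_law):
        assert permeability_field(1.0, 1e7, K_PAPER, 0.011, paper_law) < 1e-30

    def test_space_time_factorization_is_exact(self, paper_law):
        gamma = np.linspace(0.2, 3.0, 7)[:, None]
        t = np.linspace(0.0, 600.0, 9)[None, :]
        field = permeability_field(gamma, t, K_PAPER, 0.011, paper_law)
        factored = permeability_field(gamma, 0.0, K_PAPER, 0.011, paper_law) * np.exp(-K_PAPER * t)
        npt.assert_allclose(field, factored, rtol=1e-14)

    def test_monotone_nonincreasing_in_time_and_distance(self, paper_law):
        gamma = np.linspace(0.2, 3.0, 20)[:, None]
        t = np.linspace(0.0, 600.0, 20)[None, :]
        field = permeability_field(gamma, t, K_PAPER, 0.011, paper_law)
        assert np.all(np.diff(field, axis=0) <= 0)
        assert np.all(np.diff(field, axis=1) <= 0)

    def test_nonpositive_gamma_rejected(self, paper_law):
        with pytest.raises(ValueError):
            permeability_field(0.0, 0.0, K_PAPER, 0.011, paper_law)


class TestDamageFraction:
    def test_totally_damaged_cell_at_collapse(self, consts):
        law = RadialIntensityLaw.from_coefficients(2500.0, 0.0)
        s = damage_fraction(1.0, 0.0, K_PAPER, 0.011, law, consts.p0)
        assert s == pytest.approx(1.0)

    def test_brighter_than_reference_capped_at_one(self, consts, paper_law):
        # near the center the plateau exceeds 2500 AU
        s = damage_fraction(0.05, 0.0, K_PAPER, 0.011, paper_law, consts.p0)
        assert s == 1.0

    def test_decays_to_zero(self, consts, paper_law):
        assert damage_fraction(1.0, 1e7, K_PAPER, 0.011, paper_law, consts.p0) < 1e-20

    def test_time_decay_is_gamma_independent(self, consts, paper_law):
        t = 300.0
        for gamma in (1.5, 2.0, 3.0):  # uncapped region
            s0 = damage_fraction(gamma, 0.0, K_PAPER, 0.011, paper_law, consts.p0)
            st_ = damage_fraction(gamma, t, K_PAPER, 0.011, paper_law, consts.p0)
            if s0 < 1.0:
                assert st_ / s0 == pytest.approx(np.exp(-K_PAPER * t), rel=1e-12)

    def test_raw_value_matches_relative_permeability(self, consts, paper_law):
        gamma, t = 1.3, 120.0
        raw = damage_fraction(gamma, t, K_PAPER, 0.011, paper_law, consts.p0, raw=True)
        p_rel = permeability_field(gamma, t, K_PAPER, 0.011, paper_law) / consts.p0
        assert raw == pytest.approx(p_rel, rel=1e-12)


class TestAnalyticSolution:
    def test_initial_conditions(self, consts, paper_law):
        c1, c2 = solve_goldman_analytic(np.array([0.5, 1.0, 2.0]), 0.0, consts,
                                        paper_law, 0.011)
        npt.assert_allclose(c1, 1.0)
        npt.assert_allclose(c2, 0.0)

    def test_long_time_limit(self, paper_law):
        p = GoldmanParams(kappa_override=8.68e5)
        c = derive_constants(p, K_PAPER)
        c1, _ = solve_goldman_analytic(np.array([1.0]), 1e6, c, paper_law, 0.011)
        expected = np.exp(-(c.phi * 0.011 / c.kappa) * 549.0)
        assert c1[0, 0] == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        log_prefactor=st.floats(min_value=-8, max_value=1),
        theta=st.floats(min_value=0.1, max_value=20.0),
    )
    def test_uptake_monotone_in_time_over_parameter_draws(self, log_prefactor, theta):
        params = GoldmanParams(kappa_override=9.67 * 0.011 / 10**log_prefactor)
        consts = dataclasses.replace(
            derive_constants(params, K_PAPER), theta=theta,
        )
        law = RadialIntensityLaw.from_coefficients(321.0, 228.0)
        t = np.linspace(0.0, 1.0, 50)
        _, c2 = solve_goldman_analytic(np.array([0.3, 1.0, 3.0]), t, consts, law, 0.011)
        assert np.all(np.diff(c2, axis=1) >= -1e-15)


class TestNumericSolver:
    def test_alpha_zero_keeps_outside_concentration_stationary(self, params, consts, paper_law):
        frozen = dataclasses.replace(consts, alpha=0.0)
        c1, c2 = solve_goldman_numeric(params, frozen, paper_law, 0.011,
                                       np.linspace(0.2, 3, 5), np.linspace(0, 600, 7))
        npt.assert_allclose(c1, 1.0, atol=1e-12)

    def test_matches_closed_form_with_nernst_term_dropped(self, paper_law):
        """Independent ODE integration vs the separable closed form."""
        phi = derive_constants(GoldmanParams(), K_PAPER).phi
        # moderate-exponent regime: max exponent ~5 at the inner edge
        p = GoldmanParams(kappa_override=phi * 0.011 * 1950.0 / 5.0)
        c = derive_constants(p, K_PAPER)
        c_no_nernst = dataclasses.replace(c, alpha_m=0.0)
        gamma = np.linspace(0.14, 3.0, 50)
        t = np.linspace(0.0, 600.0, 200)
        c1n, _ = solve_goldman_numeric(p, c_no_nernst, paper_law, 0.011, gamma, t)
        c1a, _ = solve_goldman_analytic(gamma, t / p.T_obs, c, paper_law, 0.011)
        assert np.max(np.abs(c1n - c1a) / np.abs(c1a)) <= 1e-6

    def test_conservation_holds_everywhere(self, params, consts, paper_law):
        c1, c2 = solve_goldman_numeric(params, consts, paper_law, 0.011,
                                       np.linspace(0.14, 3, 20), np.linspace(0, 600, 50))
        assert np.max(np.abs(c1 + c2 - 1.0)) <= 1e-8

    def test_volume_fraction_bookkeeping_breaks_conservation(self, params, paper_law):
        p = GoldmanParams(kappa_override=8.68e5)
        c = derive_constants(p, K_PAPER)
        c1, c2 = solve_goldman_numeric(p, c, paper_law, 0.011,
                                       np.array([0.5]), np.linspace(0, 600, 20),
                                       continuity="volume_fraction")
        # (β−1)/β = −1.44 for β = 0.41: the inside gains more than the outside loses
        drift = c1 + c2 - 1.0
        assert np.max(drift) > 0
        npt.assert_allclose(c2[:, -1], ((p.beta - 1) / p.beta) * (c1[:, -1] - 1.0),
                            rtol=1e-6)

    def test_empty_grid_rejected(self, params, consts, paper_law):
        with pytest.raises(ValueError):
            solve_goldman_numeric(params, consts, paper_law, 0.011, [], [0.0])


class TestLinearization:
    def test_zero_at_time_origin(self, paper_law):
        p = GoldmanParams(kappa_override=8.68e5)
        c = derive_constants(p, K_PAPER)
        c2 = c2_linearized(np.array([1.0]), 0.0, c, paper_law, 0.011)
        assert c2[0, 0] == 0.0

    def test_taylor_remainder_bound_in_validity_regime(self, paper_law):
        """|c2_lin − c2_exact| ≤ x²/2 when the expansion parameter x ≤ 0.1."""
        phi = derive_constants(GoldmanParams(), K_PAPER).phi
        p = GoldmanParams(kappa_override=phi * 0.011 * 1950.0 / 0.1)
        c = derive_constants(p, K_PAPER)
        gamma = np.linspace(0.14, 3.0, 30)
        t = np.linspace(0.0, 1.0, 40)
        _, c2_exact = solve_goldman_analytic(gamma, t, c, paper_law, 0.011)
        c2_lin = c2_linearized(gamma, t, c, paper_law, 0.011)
        x = (c.phi * 0.011 / c.kappa) * paper_law.predict(gamma)[:, None] \
            * (1.0 - np.exp(-c.theta * t)[None, :])
        assert np.max(x) <= 0.1 + 1e-12
        assert np.all(np.abs(c2_lin - c2_exact) <= x**2 / 2.0 + 1e-15)

    def test_shape_identity_with_saturation_curve(self, paper_law):
        p = GoldmanParams(kappa_override=8.68e5)
        c = derive_constants(p, K_PAPER)
        t = np.linspace(0.0, 1.0, 25)
        c2 = c2_linearized(np.array([1.0]), t, c, paper_law, 0.011)
        c2_inf = c2_linearized(np.array([1.0]), 1e9, c, paper_law, 0.011)
        npt.assert_allclose(c2[0] / c2_inf[0, 0], 1.0 - np.exp(-c.theta * t), rtol=1e-10)

    def test_warns_outside_validity_regime(self, consts, paper_law):
        with pytest.warns(RuntimeWarning, match="linearization"):
            c2_linearized(np.array([1.0]), 0.5, consts, paper_law, 0.011)


class TestCalibration:
    def test_k2_satisfies_unity_relation(self, params, consts):
        k2 = calibrate_k2(params, consts)
        assert consts.phi * params.k1 * k2 * params.c0 / consts.kappa == pytest.approx(1.0, rel=1e-14)

    def test_doubling_concentration_halves_k2(self, params, consts):
        k2 = calibrate_k2(params, consts)
        double = params.with_overrides(c0=2 * params.c0)
        assert calibrate_k2(double, derive_constants(double, K_PAPER)) == pytest.approx(k2 / 2)

    def test_potential_round_trip_to_machine_precision(self, params, consts):
        k2 = calibrate_k2(params, consts)
        recovered = transmembrane_potential(params, params.k1, k2)
        assert recovered == pytest.approx(params.dPhi_m, rel=1e-12)

    def test_potential_inverse_in_concentration_and_valence(self, params, consts):
        k2 = calibrate_k2(params, consts)
        base = transmembrane_potential(params, params.k1, k2)
        double_c0 = params.with_overrides(c0=2 * params.c0)
        assert transmembrane_potential(double_c0, params.k1, k2) == pytest.approx(base / 2)
        double_z = params.with_overrides(z=2 * params.z)
        assert transmembrane_potential(double_z, params.k1, k2) == pytest.approx(base / 2)


class TestFieldMap:
    def test_long_format_round_trip(self, params, paper_law, tmp_path):
        fm = build_field_map(params, K_PAPER, paper_law,
                             np.linspace(0.2, 3, 4), np.linspace(0, 600, 5))
        df = fm.to_dataframe()
        assert len(df) == 4 * 5
        assert set(df.columns) == {"gamma", "t_s", "I", "P_over_p0", "S_p", "c1", "c2"}
        npt.assert_allclose(df["c1"] + df["c2"], 1.0, atol=1e-8)
        assert ((df["S_p"] >= 0) & (df["S_p"] <= 1)).all()

    def test_single_point_grid(self, params, paper_law):
        fm = build_field_map(params, K_PAPER, paper_law, [1.0], [0.0])
        assert fm.I.shape == (1, 1)
        assert fm.I[0, 0] == 0.0  # no uptake at the instant of collapse
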