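"""Relaxation times, thermal mapping, transition solvers, fitting."""

import numpy as np
import pytest
from scipy.special import spherical_jn

import ecnle.kinetics as kinetics
from ecnle import (
    MATERIALS,
    ConfigurationError,
    DomainError,
    FluidState,
    MaterialModel,
    RangeError,
    alpha_time,
    beta_time,
    compute_structure,
    compute_timescales,
    extract_diameter,
    fit_material_parameters,
    get_isobar,
    glass_transition_pressure,
    glass_transition_temperature,
    phi_from_temperature,
    pressure_scan,
    short_time_scale,
    tau_curve_vs_temperature,
    thermal_map,
)


class TestShortTime:
    def test_binary_collision_vertex_at_pi(self):
        # 1 - j0(pi) + 2 j2(pi) = 1 + 6/pi^2
        denom = 1 - spherical_jn(0, np.pi) + 2 * spherical_jn(2, np.pi)
        assert denom == pytest.approx(1.608, abs=1e-3)
        assert denom == pytest.approx(1 + 6 / np.pi**2, rel=1e-12)

    def test_dilute_limit_is_enskog(self):
        assert short_time_scale(FluidState(1e-8)) == pytest.approx(1.0, abs=1e-5)

    def test_grows_with_structure(self):
        t52 = short_time_scale(FluidState(0.52))
        t58 = short_time_scale(FluidState(0.58))
        assert 1 < t52 < t58


class TestKramersTimes:
    def test_alpha_equals_beta_without_coupling(self, structure_055, state_055):
        uncoupled = MaterialModel("x", t0=500.0, ac=0.0)
        ta = alpha_time(state_055, structure_055, uncoupled)
        tb = beta_time(state_055, structure_055)
        assert ta == pytest.approx(tb, rel=1e-12)

    def test_beta_never_exceeds_alpha(self, curcumin):
        for phi in (0.50, 0.55, 0.60):
            for pstar in (0.0, 1.8):
                st = compute_structure(phi)
                ts = compute_timescales(FluidState(phi, pstar), st, curcumin)
                assert ts.tau_beta <= ts.tau_alpha
                assert ts.tau_s >= ts.tau_e

    def test_compression_slows_both_processes(self, structure_055, curcumin):
        ts = [
            compute_timescales(FluidState(0.55, p), structure_055, curcumin)
            for p in (0.0, 1.0, 2.0)
        ]
        for a, b in zip(ts, ts[1:]):
            assert b.tau_alpha > a.tau_alpha
            assert b.tau_beta > a.tau_beta

    def test_stronger_coupling_slows_alpha(self, structure_055, state_055):
        taus = [
            alpha_time(state_055, structure_055, MaterialModel("x", t0=500.0, ac=ac))
            for ac in (0.5, 1.0, 1.5)
        ]
        assert taus[0] < taus[1] < taus[2]

    def test_reduced_units_independent_of_diameter(self, structure_055, curcumin):
        t1 = alpha_time(FluidState(0.55, 1.0, d=1.0), structure_055, curcumin)
        t2 = alpha_time(FluidState(0.55, 1.0, d=0.449), structure_055, curcumin)
        assert t1 == pytest.approx(t2, rel=1e-14)


class TestThermalMap:
    def test_reference_point(self, curcumin):
        assert thermal_map(0.5, curcumin) == pytest.approx(curcumin.t0, rel=1e-14)

    def test_curcumin_example(self, curcumin):
        # 518.6 - 0.06/(12e-4 * 0.5)
        assert thermal_map(0.56, curcumin) == pytest.approx(418.6, abs=1e-9)

    def test_roundtrip_exact(self, curcumin):
        for phi in (0.50, 0.55, 0.62):
            T = thermal_map(phi, curcumin)
            assert phi_from_temperature(T, curcumin) == pytest.approx(phi, abs=1e-12)

    def test_constant_slope(self, curcumin):
        s1 = thermal_map(0.52, curcumin) - thermal_map(0.51, curcumin)
        s2 = thermal_map(0.61, curcumin) - thermal_map(0.60, curcumin)
        expected = -0.01 / (curcumin.beta_glass * curcumin.phi0)
        assert s1 == pytest.approx(expected, rel=1e-9)
        assert s2 == pytest.approx(expected, rel=1e-9)

    def test_beta_process_under_pressure_needs_crystal_coefficient(self, curcumin):
        with pytest.raises(ConfigurationError):
            thermal_map(0.55, curcumin, which="beta", pstar=1.8)
        with_crystal = MaterialModel("x", t0=500.0, ac=1.0, beta_crystal=4.72e-4)
        assert thermal_map(0.55, with_crystal, which="beta", pstar=1.8) < 500.0

    def test_crystal_coefficient_must_be_smaller(self):
        with pytest.raises(DomainError):
            MaterialModel("x", t0=500.0, ac=1.0, beta_crystal=13e-4)


class TestDiameterExtraction:
    def test_cube_root_temperature_scaling(self):
        assert extract_diameter(1.8, 100.0, 8 * 365.0) == pytest.approx(
            2 * extract_diameter(1.8, 100.0, 365.0), rel=1e-12
        )

    def test_no_length_scale_at_zero_pressure(self):
        with pytest.raises(DomainError):
            extract_diameter(0.0, 100.0, 365.0)


class TestTauCurves:
    def test_alpha_dominates_and_slows_on_cooling(self, curcumin):
        df = tau_curve_vs_temperature(curcumin, 0.0)
        assert (df.log10_tau_alpha_s >= df.log10_tau_beta_s).all()
        # log10 tau decreases with T (increases on cooling)
        ordered = df.sort_values("temperature_K")
        assert (np.diff(ordered.log10_tau_alpha_s) < 0).all()
        assert (np.diff(ordered.log10_tau_beta_s) < 0).all()

    def test_super_arrhenius_curvature(self, curcumin):
        from scipy.interpolate import CubicSpline

        df = tau_curve_vs_temperature(curcumin, 0.0)
        x = 1.0 / df.temperature_K.values
        y = df.log10_tau_alpha_s.values
        order = np.argsort(x)
        spl = CubicSpline(x[order], y[order])
        xi = np.linspace(x.min(), x.max(), 200)[1:-1]
        # activation slope vs 1/T grows on cooling: positive curvature
        assert (spl(xi, 2) > 0).all()

    def test_compressed_curve_lies_above(self, curcumin):
        df0 = tau_curve_vs_temperature(curcumin, 0.0).sort_values("temperature_K")
        df1 = tau_curve_vs_temperature(curcumin, 1.8).sort_values("temperature_K")
        t_common = np.linspace(
            max(df0.temperature_K.min(), df1.temperature_K.min()),
            min(df0.temperature_K.max(), df1.temperature_K.max()),
            20,
        )
        y0 = np.interp(t_common, df0.temperature_K, df0.log10_tau_alpha_s)
        y1 = np.interp(t_common, df1.temperature_K, df1.log10_tau_alpha_s)
        assert (y1 > y0).all()

    def test_decoupling_grows_on_cooling(self, curcumin):
        df = tau_curve_vs_temperature(curcumin, 0.0).sort_values("temperature_K", ascending=False)
        ratio = df.log10_tau_alpha_s.values - df.log10_tau_beta_s.values
        assert (np.diff(ratio) > -1e-9).all()


class TestGlassTransition:
    def test_tg_hits_threshold(self, curcumin):
        tg = glass_transition_temperature(curcumin, 0.0)
        model = get_isobar(0.0)
        phi_g = phi_from_temperature(tg, curcumin)
        resid = model.log10_tau_alpha(phi_g, curcumin.ac) - np.log10(curcumin.tg_threshold)
        assert abs(resid) < 1e-3

    def test_compression_raises_tg(self, curcumin):
        assert glass_transition_temperature(curcumin, 2.0) > glass_transition_temperature(
            curcumin, 0.0
        )

    def test_weaker_coupling_lowers_tg(self):
        # shared 0.1 s threshold so both couplings reach it in the window
        strong = MaterialModel("x", t0=518.6, ac=1.0, tg_threshold=0.1)
        weak = MaterialModel("y", t0=518.6, ac=0.8, tg_threshold=0.1)
        assert glass_transition_temperature(weak) < glass_transition_temperature(strong)

    def test_pg_hits_threshold(self, curcumin):
        pg = glass_transition_pressure(curcumin, 375.0)
        phi_t = phi_from_temperature(375.0, curcumin)
        resid = kinetics._log10_tau_alpha_state(phi_t, pg, curcumin.ac) - np.log10(
            curcumin.tg_threshold
        )
        assert abs(resid) < 1e-3

    def test_hotter_liquid_needs_more_compression(self, curcumin):
        assert glass_transition_pressure(curcumin, 389.0) > glass_transition_pressure(
            curcumin, 361.0
        )

    def test_already_glassy_is_range_error(self, curcumin):
        with pytest.raises(RangeError):
            glass_transition_pressure(curcumin, 310.0)

    def test_normalized_scan_passes_through_threshold(self, curcumin):
        df = pressure_scan(curcumin, 375.0, n=5, span=1.0)
        last = df.iloc[-1]
        assert last.p_over_pg == pytest.approx(1.0, abs=1e-12)
        assert last.log10_tau_alpha_s == pytest.approx(
            np.log10(curcumin.tg_threshold), abs=1e-3
        )


@pytest.fixture(scope="module")
def synthetic_noiseless():
    model = get_isobar(0.0)
    temps = np.linspace(330.0, 420.0, 25)
    phis = 0.5 * (1 + 12e-4 * (518.6 - temps))
    return np.column_stack([temps, model.log10_tau_alpha(phis, 1.0)])


class TestFitting:
    def test_noiseless_recovery_is_exact(self, synthetic_noiseless):
        res = fit_material_parameters(synthetic_noiseless)
        assert res.t0 == pytest.approx(518.6, abs=1e-6)
        assert res.ac == pytest.approx(1.0, abs=1e-8)
        assert res.residual_norm < 1e-8

    def test_fixed_coupling_reduces_to_one_parameter(self, synthetic_noiseless):
        res = fit_material_parameters(synthetic_noiseless, ac_fixed=1.0)
        assert res.ac == 1.0
        assert res.t0 == pytest.approx(518.6, abs=1e-6)

    def test_requires_enough_observations(self):
        with pytest.raises(Exception):
            fit_material_parameters(np.zeros((3, 2)))
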