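"""Pressure-profile metrics and fluctuation bending moduli."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

from blistertools.core import BeadFrame
from blistertools.errors import (
    ConfigurationError,
    ContractError,
    FitError,
    ParseError,
)
from blistertools.mechanics import (
    PressureProfile,
    chain_pressure,
    combine_replicas,
    curvature_stress,
    extract_height_field,
    first_moment_curvature,
    glycerol_minima,
    kappa_fourier,
    kappa_realspace,
    load_stress_table,
    stress_metrics,
    tension,
)
from blistertools.synth import gen_helfrich_fields, gen_stress_profile


def profile_from_pi(z, pi, **kw):
    return PressureProfile(z=z, p_n=np.zeros_like(z), p_t=np.asarray(pi, dtype=float), **kw)


class TestLoadStressTable:
    def test_pressure_table_with_equal_components(self, tmp_path):
        p = tmp_path / "flat.dat"
        rows = "\n".join(f"{z:.2f} 50 50 50" for z in np.arange(-3, 3.01, 0.1))
        p.write_text("# z pxx pyy pzz\n" + rows + "\n")
        prof = load_stress_table(p)
        np.testing.assert_allclose(prof.pi, 0.0)

    def test_stress_volume_conversion(self, tmp_path):
        p = tmp_path / "sv.dat"
        rows = "\n".join(f"{z:.2f} -1000 -1000 0" for z in np.arange(-3, 3.01, 0.1))
        p.write_text("# slab_volume 10\n# z sxx syy szz\n" + rows + "\n")
        prof = load_stress_table(p, convention="stress-volume", recenter=False)
        np.testing.assert_allclose(prof.p_t, 100.0)
        np.testing.assert_allclose(prof.p_n, 0.0)
        np.testing.assert_allclose(prof.pi, 100.0)

    def test_offset_profile_recentered(self, tmp_path):
        prof0, _ = gen_stress_profile(dz=0.01)
        p = tmp_path / "off.dat"
        rows = "\n".join(
            f"{z + 2.0:.5f} {pt:.6f} {pt:.6f} 0.0"
            for z, pt in zip(prof0.z, prof0.p_t)
        )
        p.write_text("# z pxx pyy pzz\n" + rows + "\n")
        prof = load_stress_table(p)
        z1, z2 = glycerol_minima(prof)
        assert z1 == pytest.approx(-z2, abs=0.02)

    def test_non_monotone_z_rejected(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("# z pxx pyy pzz\n0.0 1 1 1\n0.0 1 1 1\n")
        with pytest.raises(ParseError):
            load_stress_table(p)

    def test_missing_slab_volume_rejected(self, tmp_path):
        p = tmp_path / "sv.dat"
        p.write_text("# z sxx syy szz\n-1 0 0 0\n0 0 0 0\n1 0 0 0\n")
        with pytest.raises(ConfigurationError):
            load_stress_table(p, convention="stress-volume")


class TestChainPressure:
    def test_zero_profile(self):
        z = np.arange(-4, 4.0005, 0.001)
        val, sd = chain_pressure(profile_from_pi(z, np.zeros_like(z)), minima=(-2, 2))
        assert val == 0.0 and sd == 0.0

    def test_gaussian_closed_form(self):
        a_amp, sigma = 100.0, 0.5
        z = np.arange(-4, 4.0005, 0.001)
        pi = a_amp * np.exp(-(z**2) / (2 * sigma**2))
        val, _ = chain_pressure(profile_from_pi(z, pi), minima=(-2.0, 2.0))
        expected = 0.1 * a_amp * sigma * math.sqrt(2 * math.pi) * erf(2.0 / (sigma * math.sqrt(2)))
        assert val == pytest.approx(expected, rel=1e-6)

    def test_positive_lobe_outside_window_ignored(self):
        z = np.arange(-5, 5.0005, 0.001)
        pi = 80.0 * np.exp(-((np.abs(z) - 3.5) ** 2) / 0.02)
        val, _ = chain_pressure(profile_from_pi(z, pi), minima=(-2.0, 2.0))
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_generated_lobes_match_analytic_reference(self):
        for form in ("gaussian-lobes", "piecewise"):
            prof, refs = gen_stress_profile(form=form)
            val, _ = chain_pressure(prof)
            assert val == pytest.approx(refs["pi_ch_mN_m"], rel=1e-6)

    def test_minima_must_straddle_midplane(self):
        z = np.arange(-4, 4.0005, 0.001)
        with pytest.raises(ContractError):
            chain_pressure(profile_from_pi(z, np.ones_like(z)), minima=(1.0, 2.0))

    def test_replica_sd(self):
        prof1, _ = gen_stress_profile()
        prof2, _ = gen_stress_profile()
        combined = combine_replicas([prof1, prof2])
        combined.minima = prof1.minima
        val, sd = chain_pressure(combined)
        assert sd == pytest.approx(0.0, abs=1e-12)


class TestFirstMoment:
    def test_even_pairing_cancels_moment(self):
        # odd-in-z lobe pairs within each leaflet: zero first moment
        z = np.arange(-4, 4.0005, 0.001)
        pi = np.zeros_like(z)
        for c, s in ((1.0, 0.2), (3.0, 0.2)):
            pi += np.exp(-((np.abs(z) - c) ** 2) / (2 * s**2))
        pi -= 2 * np.exp(-((np.abs(z) - 2.0) ** 2) / (2 * 0.2**2))
        prof = profile_from_pi(z, 100 * pi, l_z=8.0)
        fm = first_moment_curvature(prof, kappa_b_kT=10.0)
        # symmetric leaflets agree
        assert fm.kb_c0_upper == pytest.approx(fm.kb_c0_lower, abs=1e-9)

    def test_constant_lobe_polynomial_integral(self):
        z = np.arange(-3, 3.0005, 0.001)
        pi = np.where((z >= 0) & (z <= 2.0), 100.0, 0.0)
        prof = profile_from_pi(z, pi, l_z=6.0)
        fm = first_moment_curvature(prof, kappa_b_kT=10.0)
        assert fm.kb_c0_upper == pytest.approx(-20.0, rel=1e-3)

    def test_generated_profiles_match_analytic_reference(self):
        for form in ("gaussian-lobes", "piecewise"):
            prof, refs = gen_stress_profile(form=form)
            fm = first_moment_curvature(prof, kappa_b_kT=10.0)
            assert fm.kb_c0_upper == pytest.approx(refs["moment_upper_mN_m_nm"], rel=1e-6)
            assert fm.kb_c0_lower == pytest.approx(refs["moment_lower_mN_m_nm"], rel=1e-6)

    def test_asymmetric_profile_flags_leaflet_difference(self):
        prof, refs = gen_stress_profile(asymmetry=0.3)
        fm = first_moment_curvature(prof, kappa_b_kT=10.0)
        assert refs["asymmetric"]
        assert abs(fm.asymmetry) > 1.0

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(
        a=st.floats(-2.0, 2.0),
        b=st.floats(-2.0, 2.0),
    )
    def test_first_moment_linearity(self, a, b):
        prof1, _ = gen_stress_profile(chain_amp=200.0, dz=0.01)
        prof2, _ = gen_stress_profile(chain_amp=150.0, chain_pos=1.0, dz=0.01)
        mix = profile_from_pi(prof1.z, a * prof1.pi + b * prof2.pi, l_z=prof1.l_z)
        m_mix = first_moment_curvature(mix, 10.0).kb_c0_upper
        m1 = first_moment_curvature(prof1, 10.0).kb_c0_upper
        m2 = first_moment_curvature(prof2, 10.0).kb_c0_upper
        assert m_mix == pytest.approx(a * m1 + b * m2, abs=1e-9)

    def test_c0_unit_conversion(self):
        # kb_c0 = 4.28 mN/m nm with kappa_b = 1 kT at 310 K -> c0 = 1 nm^-1
        z = np.arange(-3, 3.0005, 0.001)
        pi = np.where((z >= 0) & (z <= 2.0), -2.14, 0.0)  # moment = +4.28/10
        prof = profile_from_pi(z, pi * 10, l_z=6.0)
        fm = first_moment_curvature(prof, kappa_b_kT=1.0)
        assert fm.c0 == pytest.approx(fm.kb_c0 / 4.28, rel=1e-3)

    def test_grid_must_span_leaflet(self):
        z = np.arange(-1, 1.0005, 0.001)
        prof = profile_from_pi(z, np.zeros_like(z), l_z=8.0)
        with pytest.raises(ConfigurationError):
            first_moment_curvature(prof, 10.0)


class TestCurvatureStress:
    def test_zero_curvature(self):
        assert curvature_stress(10.0, 0.0)[0] == 0.0

    def test_arithmetic(self):
        assert curvature_stress(10.0, 0.1)[0] == pytest.approx(0.1)

    def test_quadratic_in_c0(self):
        s1 = curvature_stress(10.0, 0.05)[0]
        s2 = curvature_stress(10.0, 0.10)[0]
        assert s2 == pytest.approx(4 * s1)

    def test_error_propagation(self):
        val, sd = curvature_stress(10.0, 0.1, kappa_b_sd=1.0, c0_sd=0.01)
        assert sd == pytest.approx(
            math.hypot(0.1**2 * 1.0, 2 * 10.0 * 0.1 * 0.01)
        )


class TestZeroTension:
    def test_tensionless_fixture_below_tolerance(self):
        prof, refs = gen_stress_profile()
        assert abs(tension(prof)) < 0.1
        assert refs["tension_mN_m"] == pytest.approx(0.0, abs=1e-12)

    def test_net_tension_warns(self):
        prof, _ = gen_stress_profile(zero_tension=False)
        with pytest.warns(UserWarning, match="tension"):
            tension(prof)


def bilayer_height_frame(nx=600, amp=0.0, mode=1, box_l=30.0, seed=0):
    """Single-bead-per-leaflet glycerol sheet with optional sinusoid in z."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, box_l, (nx, 2))
    h = amp * np.sin(2 * np.pi * mode * pts[:, 0] / box_l)
    upper = np.column_stack([pts, 10.0 + 1.5 + h])
    lower = np.column_stack([pts, 10.0 - 1.5 + h])
    coords = np.vstack([upper, lower])
    n = len(coords)
    return BeadFrame(
        time=0.0,
        box=np.array([box_l, box_l, 20.0]),
        coords=coords,
        bead_to_molecule=np.arange(n),
        molecule_to_species={i: "DOPC" for i in range(n)},
        bead_role=["glycerol"] * n,
    )


class TestHeightField:
    def test_flat_bilayer_constant_field(self):
        frame = bilayer_height_frame(amp=0.0)
        hf = extract_height_field(frame, grid=(8, 8))
        assert np.ptp(hf.mid) == pytest.approx(0.0, abs=1e-9)
        assert hf.mid[0, 0] == pytest.approx(10.0)

    def test_sinusoid_recovered(self):
        frame = bilayer_height_frame(nx=4000, amp=0.5, seed=1)
        hf = extract_height_field(frame, grid=(16, 16))
        x = (np.arange(16) + 0.5) * 30.0 / 16
        expected = 10.0 + 0.5 * np.sin(2 * np.pi * x / 30.0)
        # cell-average bias only: binning 4000 beads on 16x16 cells
        np.testing.assert_allclose(hf.mid.mean(axis=1), expected, atol=0.1)

    def test_single_cell_grid_gives_mean(self):
        frame = bilayer_height_frame(amp=0.3, seed=2)
        hf = extract_height_field(frame, grid=(1, 1))
        assert hf.mid[0, 0] == pytest.approx(frame.coords[:, 2].mean(), abs=0.05)

    def test_too_fine_grid_rejected(self):
        frame = bilayer_height_frame(nx=40)
        with pytest.raises(ConfigurationError):
            extract_height_field(frame, grid=(64, 64))


class TestKappaFourier:
    def test_recovers_generator_kappa(self):
        fields = gen_helfrich_fields(10.0, 40.0, grid=64, n_frames=256, seed=2)
        spec = kappa_fourier(fields, (40.0, 40.0))
        assert spec.kappa_kT == pytest.approx(10.0, rel=0.1)
        assert spec.kappa_b_kT == pytest.approx(spec.kappa_kT / 2)
        assert spec.slope == pytest.approx(-4.0, abs=0.6)

    def test_flat_fields_flagged(self):
        spec = kappa_fourier(np.zeros((4, 64, 64)), (40.0, 40.0))
        assert spec.no_undulation
        assert math.isinf(spec.kappa_kT)

    def test_quarter_amplitude_at_4x_kappa(self):
        f10 = gen_helfrich_fields(10.0, 40.0, grid=32, n_frames=64, seed=3)
        f40 = gen_helfrich_fields(40.0, 40.0, grid=32, n_frames=64, seed=3)
        s10 = kappa_fourier(f10, (40.0, 40.0))
        s40 = kappa_fourier(f40, (40.0, 40.0))
        np.testing.assert_allclose(s40.spectrum, s10.spectrum / 4.0, rtol=1e-10)

    def test_too_few_shells_rejected(self):
        fields = gen_helfrich_fields(10.0, 10.0, grid=16, n_frames=8, seed=0)
        with pytest.raises(FitError):
            kappa_fourier(fields, (10.0, 10.0), q_max=0.8)


class TestKappaRealspace:
    def test_cross_estimator_agreement(self):
        fields = gen_helfrich_fields(10.0, 40.0, grid=64, n_frames=256, seed=4)
        kf = kappa_fourier(fields, (40.0, 40.0)).kappa_kT
        kr = kappa_realspace(fields, (40.0, 40.0))
        assert abs(kr - kf) / kf < 0.2

    def test_flat_fields_decline_fit(self):
        with pytest.raises(FitError):
            kappa_realspace(np.zeros((4, 64, 64)), (40.0, 40.0))

    def test_ordering_of_kappas(self):
        k5 = kappa_realspace(
            gen_helfrich_fields(5.0, 40.0, grid=64, n_frames=128, seed=5), (40.0, 40.0)
        )
        k20 = kappa_realspace(
            gen_helfrich_fields(20.0, 40.0, grid=64, n_frames=128, seed=6), (40.0, 40.0)
        )
        assert k5 < k20


class TestStressMetricsBundle:
    def test_pipeline_consistency(self):
        prof, refs = gen_stress_profile()
        m = stress_metrics(prof, kappa_b_kT=10.0)
        assert m.pi_ch_mN_m == pytest.approx(refs["pi_ch_mN_m"], rel=1e-6)
        assert m.curvature_stress_kT_nm2 == pytest.approx(
            10.0 * m.c0_per_nm**2
        )
        assert abs(m.tension_mN_m) < 0.1
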