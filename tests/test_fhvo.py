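import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coacervate import fhvo
from coacervate.fhvo import (DEFAULT_PARAMS, ChiLaw, MixtureParams,
                             bitangent, bitangent_hull, binodal_curve,
                             cloud_point_temperature,
                             composition_from_conditions, electrostatic_strength,
                             fh_critical_point, fit_chi_law, fit_chi_point,
                             free_energy_per_site, lattice_length, neutral_fh,
                             reduced_free_energy, spinodal_interval)


class TestParameterization:
    def test_lattice_length_value(self):
        # l_w = (1e-3 / (55.56 mol/L * N_A))^{1/3} ~ 0.31 nm
        assert lattice_length() == pytest.approx(3.103e-10, rel=1e-3)

    def test_alpha_at_300K(self):
        # alpha = (2/3) sqrt(pi) (l_B/l_w)^{3/2} with l_B(300 K) = 0.696 nm
        assert electrostatic_strength(300.0) == pytest.approx(3.971, rel=1e-3)

    def test_composition_rules(self):
        p = DEFAULT_PARAMS
        # [tau] = 50 uM: phi = 50e-6 * 218 / 55.56
        assert p.phi_polymer(50.0) == pytest.approx(50e-6 * 218 / 55.56)
        assert p.phi_salt(100.0) == pytest.approx(120e-3 / 55.56)
        # inverses
        assert p.tau_uM(p.phi_polymer(37.0)) == pytest.approx(37.0)
        assert p.nacl_mM(p.phi_salt(88.0)) == pytest.approx(88.0)

    def test_system_sums_to_one(self):
        sys = composition_from_conditions(100.0, 100.0, T=300.0, chi=0.5)
        assert sys.phi.sum() == pytest.approx(1.0)
        assert len(sys.species) == 5

    def test_overfull_rejected(self):
        with pytest.raises(ValueError, match="water"):
            composition_from_conditions(3e6, 100.0)

    def test_free_energy_finite_and_negative_for_dilute_mix(self):
        sys = composition_from_conditions(50.0, 100.0, T=300.0, chi=0.5)
        f = free_energy_per_site(sys)
        assert np.isfinite(f)
        assert f < 0  # mixing entropy dominates at dilute composition


class TestReducedFreeEnergy:
    def test_derivatives_match_finite_differences(self):
        fe = reduced_free_energy(phi_salt=0.002, T=300.0, chi=0.6)
        for phi in (1e-6, 1e-3, 0.05, 0.3):
            h = phi * 1e-5
            fd1 = (fe.f(phi + h) - fe.f(phi - h)) / (2 * h)
            # d2f via the analytic first derivative (the double difference
            # of f cancels catastrophically at dilute phi)
            fd2 = (fe.df(phi + h) - fe.df(phi - h)) / (2 * h)
            assert fe.df(phi) == pytest.approx(fd1, rel=1e-4)
            assert fe.d2f(phi) == pytest.approx(fd2, rel=1e-4)

    def test_neutral_fh_matches_textbook_form(self):
        N, chi, phi = 100.0, 0.7, 0.2
        fe = neutral_fh(N, chi)
        expected = (phi / N * np.log(phi) + (1 - phi) * np.log(1 - phi)
                    + chi * phi * (1 - phi))
        assert fe.f(phi) == pytest.approx(expected, rel=1e-12)


class TestBitangent:
    def test_supercritical_is_single_phase(self):
        chi_c, _ = fh_critical_point(100)
        fe = neutral_fh(100, chi_c * 0.9)
        assert bitangent(fe) is None
        assert spinodal_interval(fe) is None

    def test_subcritical_pair_brackets_spinodal(self):
        chi_c, _ = fh_critical_point(100)
        fe = neutral_fh(100, chi_c * 1.2)
        pair = bitangent(fe)
        sp = spinodal_interval(fe)
        assert pair is not None and sp is not None
        assert pair.phi1 < sp[0] < sp[1] < pair.phi2

    def test_equal_slopes_and_intercepts(self):
        fe = reduced_free_energy(phi_salt=0.002, T=300.0, chi=0.55)
        pair = bitangent(fe)
        assert pair is not None
        mu1, mu2 = fe.df(pair.phi1), fe.df(pair.phi2)
        assert mu1 == pytest.approx(mu2, rel=1e-8, abs=1e-10)
        assert fe.intercept(pair.phi1) == pytest.approx(
            fe.intercept(pair.phi2), rel=1e-8, abs=1e-12)

    def test_newton_and_hull_agree(self):
        fe = reduced_free_energy(phi_salt=0.0025, T=305.0, chi=0.58)
        a, b = bitangent(fe), bitangent_hull(fe)
        assert a is not None and b is not None
        assert a.phi1 == pytest.approx(b.phi1, abs=1e-6)
        assert a.phi2 == pytest.approx(b.phi2, abs=1e-6)

    def test_symmetric_polymer_pair_is_symmetric(self):
        # N = 1 "polymer": f symmetric around 1/2, so phi1 + phi2 = 1
        fe = neutral_fh(1, 2.5)
        pair = bitangent(fe)
        assert pair is not None
        assert pair.phi1 + pair.phi2 == pytest.approx(1.0, abs=1e-9)


class TestChiFitting:
    def test_roundtrip_single_point(self):
        # chi -> cloud point composition -> chi
        fe_chi = 0.56
        phi_salt = DEFAULT_PARAMS.phi_salt(100.0)
        pair = bitangent(reduced_free_energy(phi_salt, 300.0, fe_chi))
        tau = DEFAULT_PARAMS.tau_uM(pair.phi1)
        rec = fit_chi_point(tau, 100.0, 300.0)
        assert rec == pytest.approx(fe_chi, rel=1e-6)

    def test_chi_law_regression_exact(self):
        truth = ChiLaw(A=1.8, B=-390.0)
        pts = [(T, truth(T)) for T in (285.0, 295.0, 305.0, 315.0)]
        law = fit_chi_law(pts)
        assert law.A == pytest.approx(1.8, abs=1e-9)
        assert law.B == pytest.approx(-390.0, abs=1e-6)
        assert law.r_squared == pytest.approx(1.0)
        assert law.lcst_like

    def test_chi_law_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_chi_law([(300.0, 0.5), (310.0, 0.6)])

    def test_cloud_point_none_outside_window(self):
        # UCST-like law far from any coacervation window
        law = ChiLaw(A=0.0, B=30.0)
        assert cloud_point_temperature(50.0, 100.0, law) is None


class TestBinodalCurve:
    def test_missing_points_are_nan(self):
        law = ChiLaw(A=1.8, B=-390.0)
        df = binodal_curve(law, axis="nacl", fixed=2.0,
                           values=np.array([30.0, 700.0]))
        assert len(df) == 2  # grid preserved even if some points are missing

    def test_tau_axis_output_columns(self):
        law = ChiLaw(A=1.8, B=-390.0)
        df = binodal_curve(law, axis="tau", fixed=120.0,
                           values=np.array([20.0, 60.0]))
        assert "T_cp_K" in df.columns
        assert len(df) == 2


@given(st.floats(min_value=2.0, max_value=1000.0))
def test_critical_point_closed_form_consistent(N):
    chi_c, phi_c = fh_critical_point(N)
    fe = neutral_fh(N, chi_c)
    # f'' and f''' vanish at the critical composition
    assert fe.d2f(phi_c) == pytest.approx(0.0, abs=1e-9)
    h = 1e-5
    d3 = (fe.d2f(phi_c + h) - fe.d2f(phi_c - h)) / (2 * h)
    assert abs(d3) < 1e-3 * max(1.0, chi_c)
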