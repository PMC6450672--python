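import numpy as np
import pytest

from coacervate.fhvo import bitangent, neutral_fh
from coacervate.fts import (CLDriver, FieldState, FTSModel, Mesh, build_model,
                            chemical_potential_op, density_operators,
                            dimensionless_B, dimensionless_C, dimensionless_E,
                            find_coexistence, hamiltonian, load_state,
                            neutral_fractions, pressure_op, propagate_chain,
                            run_cl, salt_density, save_state, smear,
                            zero_state)
from coacervate.sequences import ChargedSequence, load_tau, make_polyU


def neutral_chain(N=10, name="n"):
    return ChargedSequence("U" * N, (0,) * N, name)


def neutral_model(N=10, B=0.1, C=0.05, L=8.0, M=8, dt=0.01, seed=0, E=0.0):
    return build_model([neutral_chain(N), neutral_chain(N, "n2")],
                       fractions=[1.0, 0.0], B=B, E=E, C=C, L=L, M=M,
                       dt=dt, seed=seed)


class TestUnits:
    def test_dimensionless_maps(self):
        assert dimensionless_E(1.75) == pytest.approx(4 * np.pi * 1.75 * np.sqrt(6))
        assert dimensionless_B(0.25) == pytest.approx(0.25 * 6**1.5)
        assert dimensionless_C(0.22) == pytest.approx(0.22 / 6**1.5)

    def test_salt_density_120mM(self):
        # 0.12 mol/L x N_A x R0^3 with b = 4 A
        assert salt_density(120.0) == pytest.approx(3.1e-4, rel=0.02)


class TestBuildModel:
    def test_charge_ratio_tau_rna(self):
        tau = load_tau("tau187")
        rna = make_polyU(tau.N)
        fr = neutral_fractions([tau, rna])
        assert fr[0] == pytest.approx(tau.N / (tau.N + tau.q_net))
        model = build_model([tau, rna], B=0.1, E=50.0, C=0.05, L=8, M=8)
        assert model.charge_density == pytest.approx(0.0, abs=1e-15)

    def test_same_sign_chains_rejected(self):
        with pytest.raises(ValueError, match="polyanion"):
            neutral_fractions([make_polyU(5), make_polyU(5)])

    def test_counterions_patch_imbalance(self):
        tau = load_tau("tau187")
        rna = make_polyU(tau.N)
        model = build_model([tau, rna], fractions=[0.5, 0.5], B=0.1, E=10.0,
                            C=0.02, L=8, M=8)
        # RNA-heavy mixture: negative polymers need extra cations
        assert model.c_plus > 0
        assert model.charge_density == pytest.approx(0.0, abs=1e-15)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FTSModel(chains=((neutral_chain(), 0.5),), B=0.1, E=0.0, C=0.05)

    def test_zero_B_rejected(self):
        with pytest.raises(ValueError, match="excluded volume"):
            neutral_model(B=0.0)


class TestSmear:
    def test_constant_unchanged(self):
        mesh = Mesh(8.0, 8)
        f = np.full((8, 8, 8), 3.7, dtype=complex)
        np.testing.assert_allclose(smear(f, mesh), f, atol=1e-13)

    def test_mean_conserved(self, rng):
        mesh = Mesh(8.0, 8)
        f = rng.standard_normal((8, 8, 8)).astype(complex)
        assert smear(f, mesh).mean() == pytest.approx(f.mean(), abs=1e-13)

    def test_double_smear_is_wider_gaussian(self, rng):
        mesh = Mesh(12.0, 16)
        f = rng.standard_normal((16, 16, 16)).astype(complex)
        twice = smear(smear(f, mesh), mesh)
        # Gamma has spectral exp(-k^2/2); twice -> exp(-k^2), the sqrt(2)-
        # wider kernel, equal to the bond kernel
        via_bond = mesh.convolve_bond(f)
        np.testing.assert_allclose(twice, via_bond, atol=1e-12)


class TestPropagator:
    def test_zero_field_Q_is_one(self):
        mesh = Mesh(8.0, 8)
        res = propagate_chain(zero_state(mesh), neutral_chain(7), mesh)
        assert res.Q == pytest.approx(1.0 + 0j, abs=1e-14)

    def test_uniform_field_closed_form(self):
        mesh = Mesh(8.0, 8)
        st = zero_state(mesh)
        st.w += 0.23
        N = 9
        res = propagate_chain(st, neutral_chain(N), mesh)
        assert res.Q == pytest.approx(np.exp(-1j * N * 0.23), abs=1e-12)

    def test_random_walk_second_moment(self):
        # N - 1 bond steps spread a point source to variance (N-1) b^2
        mesh = Mesh(40.0, 64)
        N = 12
        q = np.zeros((64,) * 3, dtype=complex)
        q[0, 0, 0] = 1.0 / mesh.dV  # unit-mass delta at the origin
        for _ in range(N - 1):
            q = mesh.convolve_bond(q)
        x = np.fft.fftfreq(64, d=1.0 / (64 * mesh.dx))
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r2 = (X**2 + Y**2 + Z**2)
        mean_r2 = float(np.sum(r2 * q.real) * mesh.dV)
        # tolerance covers periodic wraparound of the Gaussian tails
        assert mean_r2 == pytest.approx(6.0 * (N - 1), rel=1e-3)  # b^2 = 6 R0^2

    def test_charged_monomers_see_phi(self):
        mesh = Mesh(8.0, 8)
        st = zero_state(mesh)
        st.phi_el += 0.5
        rna = make_polyU(4)
        res = propagate_chain(st, rna, mesh)
        # each z = -1 monomer contributes exp(-i z c) = exp(+0.5 i)
        assert res.Q == pytest.approx(np.exp(1j * 4 * 0.5), abs=1e-12)


class TestOperators:
    def test_hamiltonian_zero_fields(self):
        m = neutral_model()
        mesh = Mesh(m.L, m.M)
        assert hamiltonian(zero_state(mesh), m, mesh) == pytest.approx(0j)

    def test_gradient_term_gauge_invariant(self):
        m = neutral_model(E=5.0)
        mesh = Mesh(m.L, m.M)
        st = zero_state(mesh)
        st.phi_el += np.sin(2 * np.pi * np.arange(m.M) / m.M)[:, None, None]
        H1 = hamiltonian(st, m, mesh)
        st.phi_el += 1.37  # constant shift only moves ion/chain ln Q terms
        # neutral chains, no ions: H must be unchanged
        H2 = hamiltonian(st, m, mesh)
        assert H2 == pytest.approx(H1, rel=1e-10)

    def test_mean_density_is_C_at_zero_field(self):
        m = neutral_model()
        mesh = Mesh(m.L, m.M)
        rho, rho_c, Qs, _, _ = density_operators(zero_state(mesh), m, mesh)
        assert np.mean(rho).real == pytest.approx(m.C, rel=1e-12)
        np.testing.assert_allclose(rho_c, 0, atol=1e-14)

    def test_saddle_point_stationary_and_mean_field_values(self):
        N, B, C = 10, 0.1, 0.05
        m = neutral_model(N=N, B=B, C=C)
        drv = CLDriver(m)
        st = drv.init_state()
        st.w += -1j * B * C  # homogeneous saddle of the neutral system
        w_before = st.w.copy()
        drv.step(st, with_noise=False)
        np.testing.assert_allclose(st.w, w_before, atol=1e-12)
        Q = propagate_chain(st, m.chains[0][0], drv.mesh).Q
        mu = chemical_potential_op(Q, C, 1.0, N)
        assert mu.real == pytest.approx(np.log(C / N) + N * B * C, rel=1e-10)
        Pi = pressure_op(st, m, drv.mesh)
        assert Pi.real == pytest.approx(C / N + 0.5 * B * C**2, rel=1e-6)
        assert abs(Pi.imag) < 1e-12

    def test_ideal_single_beads(self):
        bead = neutral_chain(1)
        m = build_model([bead, neutral_chain(1, "b2")], fractions=[1.0, 0.0],
                        B=0.05, E=0.0, C=0.02, L=8, M=8)
        mesh = Mesh(m.L, m.M)
        mu = chemical_potential_op(1.0 + 0j, m.C, 1.0, 1)
        assert mu.real == pytest.approx(np.log(m.C))


class TestCLDynamics:
    def test_same_seed_identical(self):
        m = neutral_model(dt=0.02)
        t1 = run_cl(m, steps=60, seed=4, sample_every=10)
        t2 = run_cl(m, steps=60, seed=4, sample_every=10)
        assert t1.samples.equals(t2.samples)

    def test_different_seed_differs(self):
        m = neutral_model(dt=0.02)
        t1 = run_cl(m, steps=40, seed=4, sample_every=10)
        t2 = run_cl(m, steps=40, seed=5, sample_every=10)
        assert not t1.samples.equals(t2.samples)

    def test_gaussian_field_variance(self):
        # nearly non-interacting (C -> 0): w relaxes to the Gaussian measure
        # with per-site variance B / dV
        m = neutral_model(B=0.2, C=1e-10, dt=0.05, M=8, L=8.0)
        drv = CLDriver(m)
        st = drv.init_state()
        vals = []
        for t in range(400):
            drv.step(st)
            if t > 100:
                vals.append(np.mean(st.w.real**2))
        measured = float(np.mean(vals))
        expected = m.B / drv.mesh.dV
        assert measured == pytest.approx(expected, rel=0.1)

    def test_mean_density_equals_C(self):
        m = neutral_model(dt=0.02)
        traj = run_cl(m, steps=300, seed=1, sample_every=10)
        mean, se = traj.mean_se("density_re")
        assert mean == pytest.approx(m.C, abs=max(3 * se, 1e-9))

    def test_equilibration_discards_at_least_20pct(self):
        m = neutral_model(dt=0.02)
        traj = run_cl(m, steps=300, seed=1, sample_every=10)
        assert traj.equilibration >= 0.2 * len(traj.samples)

    def test_divergence_diagnosis(self):
        # absurdly large time step and noise blow up; the driver must say so
        pc = ChargedSequence("K" * 10, (1,) * 10, "pc")
        m = build_model([pc, make_polyU(10)], B=0.05, E=2000.0, C=5.0,
                        L=8.0, M=8, dt=50.0, seed=0)
        with pytest.raises(RuntimeError, match="smaller dt"):
            run_cl(m, steps=100, seed=0, max_restarts=2, init_noise=30.0)


class TestCoexistence:
    @staticmethod
    def branches_from_fh(N=50, chi=1.0, n=600):
        fe = neutral_fh(N, chi)
        C = np.geomspace(1e-6, 0.95, n)
        mu = fe.df(C)
        Pi = C * fe.df(C) - fe.f(C)
        return fe, C, mu, Pi

    def test_recovers_common_tangent(self):
        fe, C, mu, Pi = self.branches_from_fh()
        pair = bitangent(fe)
        pt = find_coexistence(C, mu, Pi)
        assert pt is not None
        assert pt.rho_I == pytest.approx(pair.phi1, rel=1e-2)
        assert pt.rho_II == pytest.approx(pair.phi2, rel=1e-2)
        assert pt.mu_star == pytest.approx(fe.df(pair.phi1), rel=1e-2, abs=1e-3)

    def test_monotone_branch_returns_none(self):
        fe, C, mu, Pi = self.branches_from_fh(chi=0.55)  # supercritical
        assert bitangent(neutral_fh(50, 0.55)) is None
        assert find_coexistence(C, mu, Pi) is None

    def test_rho_ordering_enforced(self):
        from coacervate.fts import CoexistencePoint
        with pytest.raises(ValueError):
            CoexistencePoint(rho_I=0.5, rho_II=0.1, mu_star=0.0, Pi_star=0.0)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        m = neutral_model()
        mesh = Mesh(m.L, m.M)
        st = zero_state(mesh)
        st.w += rng.standard_normal((m.M,) * 3)
        st.phi_el += 1j * rng.standard_normal((m.M,) * 3)
        st.step = 42
        path = tmp_path / "state.h5"
        save_state(path, st, m)
        back = load_state(path)
        assert back.step == 42
        np.testing.assert_array_equal(back.w, st.w)
        np.testing.assert_array_equal(back.phi_el, st.phi_el)
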