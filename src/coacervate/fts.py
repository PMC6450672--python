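"""Field-theoretic simulation of sequence-charged polyelectrolyte mixtures.

The particle model — discrete Gaussian chains with per-monomer charges, a
contact excluded-volume repulsion of strength v, Coulomb interactions of
range l_B, and Gaussian-smeared monomers — is transformed exactly into a
statistical field theory of two complex auxiliary fields: w (excluded-volume
channel) and phi (electrostatic channel). The complex-valued Hamiltonian

    H[w, phi] = 1/(2B) int w^2 + 1/(2E) int |grad phi|^2
                - sum_l n_l ln Q_l[w, phi]    (chains and point ions)

is sampled by complex Langevin (CL) dynamics with an exponential
time-differencing (ETD) integrator. All lengths are in units of
R0 = b / sqrt(6) (the prefactor of the ideal-chain Rg = R0 N^{1/2}); the
state is set by the dimensionless parameters B = v/R0^3, E = 4 pi l_B/R0
and the monomer density C = rho R0^3.

Coupling convention: each monomer of charge z sees the complex potential
psi_z = i Gamma*w + i z Gamma*phi with the unit Gaussian smearing kernel
Gamma (spectral form exp(-k^2 b^2 / 12)); the imaginary electrostatic
coupling is required for like charges to repel once phi is integrated out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sequences import ChargedSequence

SQRT6 = math.sqrt(6.0)


def segment_to_R0(x_in_b: float) -> float:
    """Convert a length expressed in segment units b to R0 = b/sqrt(6)."""
    return x_in_b * SQRT6


def dimensionless_E(lB_in_b: float) -> float:
    """E = 4 pi l_B / R0 from the Bjerrum length in units of b."""
    return 4.0 * np.pi * lB_in_b * SQRT6


def dimensionless_B(v_in_b3: float) -> float:
    """B = v / R0^3 from the excluded volume in units of b^3."""
    return v_in_b3 * 6.0**1.5


def dimensionless_C(rho_b3: float) -> float:
    """C = rho R0^3 from the monomer number density in units of 1/b^3."""
    return rho_b3 / 6.0**1.5


def salt_density(salt_mM: float, b: float = 4.0e-10) -> float:
    """Dimensionless number density (per R0^3) of one ion species."""
    NA = 6.02214076e23
    R0 = b / SQRT6
    return salt_mM * 1e-3 * 1e3 * NA * R0**3  # mM -> mol/m^3 -> 1/m^3 -> R0^-3


# ---------------------------------------------------------------------------
# model definition

@dataclass(frozen=True)
class FTSModel:
    """Dimensionless state of the field-theoretic simulation.

    ``chains`` pairs each :class:`ChargedSequence` with its monomer fraction
    phi_l = n_l N_l / sum_m n_m N_m. Salt enters as two point-ion species of
    fixed dimensionless densities; ``build_model`` patches any residual
    polymer charge with extra counter-ions so the box is neutral.
    """

    chains: tuple[tuple[ChargedSequence, float], ...]
    B: float
    E: float
    C: float
    c_plus: float = 0.0
    c_minus: float = 0.0
    L: float = 34.0
    M: int = 32
    dt: float = 0.01
    lambda_w: float = 1.0
    lambda_phi: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = sum(f for _, f in self.chains)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("chain fractions must sum to 1")
        if self.B <= 0:
            raise ValueError("excluded volume B must be positive "
                             "(the w-channel Hamiltonian is ill-defined at B = 0)")
        if min(self.C, self.L, self.M, self.dt) <= 0:
            raise ValueError("C, L, M, dt must be positive")
        if self.c_plus < 0 or self.c_minus < 0:
            raise ValueError("ion densities must be non-negative")
        q = self.charge_density
        if abs(q) > 1e-9 * max(self.C, 1.0):
            raise ValueError(f"box is not charge-neutral (residual {q:.3e})")

    @property
    def V(self) -> float:
        return self.L**3

    @property
    def chain_number_density(self) -> float:
        """sum_l n_l / V = C sum_l phi_l / N_l."""
        return self.C * sum(f / seq.N for seq, f in self.chains)

    @property
    def charge_density(self) -> float:
        """Net charge per volume including ions (zero for a valid model)."""
        poly = self.C * sum(f * seq.q_net / seq.N for seq, f in self.chains)
        return poly + self.c_plus - self.c_minus

    @property
    def nu(self) -> tuple[float, ...]:
        """Chain mole fractions, the charge-neutral combination weights."""
        dens = [self.C * f / seq.N for seq, f in self.chains]
        tot = sum(dens)
        return tuple(d / tot for d in dens)


def neutral_fractions(chains: Sequence[ChargedSequence]) -> tuple[float, ...]:
    """Monomer fractions of a polycation/polyanion pair at 1:1 charge ratio.

    For chains (q1 > 0, q2 < 0): n1 |q2| = n2 q1, hence
    phi_l proportional to N_l x (opposite charge). With equal chain lengths
    and a fully charged polyanion this reduces to phi_1 = N / (N + q_1).
    """
    if len(chains) != 2:
        raise ValueError("charge-ratio rule needs exactly two chain types")
    q1, q2 = chains[0].q_net, chains[1].q_net
    if q1 * q2 >= 0:
        raise ValueError("need one polycation and one polyanion for a "
                         "1:1 charge ratio")
    n1, n2 = abs(q2), abs(q1)
    w1, w2 = n1 * chains[0].N, n2 * chains[1].N
    tot = w1 + w2
    return (w1 / tot, w2 / tot)


def build_model(chains: Sequence[ChargedSequence],
                fractions: Sequence[float] | str = "charge_ratio",
                B: float = 1.0, E: float = 10.0, C: float = 0.1,
                salt_mM: float = 0.0, b: float = 4.0e-10,
                L: float = 34.0, M: int = 32, dt: float = 0.01,
                seed: int = 0) -> FTSModel:
    """Assemble a charge-neutral FTSModel.

    ``fractions='charge_ratio'`` sets the chain fractions so the polymers
    neutralize each other (the 1:1 charge-ratio preparation). With explicit
    fractions, any residual polymer charge is absorbed by extra counter-ions
    on top of the added salt; if that would require a negative ion density
    the model is rejected.
    """
    if isinstance(fractions, str):
        if fractions != "charge_ratio":
            raise ValueError(f"unknown fraction rule {fractions!r}")
        fr = neutral_fractions(chains)
    else:
        fr = tuple(float(f) for f in fractions)
    cs = salt_density(salt_mM, b)
    poly_charge = C * sum(f * seq.q_net / seq.N for seq, f in zip(chains, fr))
    c_plus = cs + max(-poly_charge, 0.0)
    c_minus = cs + max(poly_charge, 0.0)
    if min(c_plus, c_minus) < 0:
        raise ValueError("irreconcilable charge imbalance")
    pairs = tuple((seq, f) for seq, f in zip(chains, fr) if f > 0)
    return FTSModel(chains=pairs, B=B, E=E, C=C,
                    c_plus=c_plus, c_minus=c_minus, L=L, M=M, dt=dt, seed=seed)


# ---------------------------------------------------------------------------
# mesh and field state

class Mesh:
    """Periodic collocation mesh with cached spectral kernels."""

    def __init__(self, L: float, M: int):
        self.L, self.M = float(L), int(M)
        self.dx = self.L / self.M
        self.dV = self.dx**3
        self.V = self.L**3
        k1 = 2.0 * np.pi * np.fft.fftfreq(self.M, d=self.dx)
        kx, ky, kz = np.meshgrid(k1, k1, k1, indexing="ij")
        self.k2 = kx**2 + ky**2 + kz**2
        self.bond_k = np.exp(-self.k2)        # exp(-k^2 b^2/6), b^2 = 6 R0^2
        self.gamma_k = np.exp(-self.k2 / 2.0)  # exp(-k^2 b^2/12)

    def convolve_bond(self, f: np.ndarray, bond_k: np.ndarray | None = None) -> np.ndarray:
        kernel = self.bond_k if bond_k is None else bond_k
        return np.fft.ifftn(kernel * np.fft.fftn(f))

    def smear(self, f: np.ndarray, gamma_k: np.ndarray | None = None) -> np.ndarray:
        kernel = self.gamma_k if gamma_k is None else gamma_k
        return np.fft.ifftn(kernel * np.fft.fftn(f))


def smear(field: np.ndarray, mesh: Mesh) -> np.ndarray:
    """Gaussian smearing Gamma * field; conserves the spatial mean."""
    return mesh.smear(field)


@dataclass
class FieldState:
    """The two complex auxiliary fields on the mesh."""

    w: np.ndarray
    phi_el: np.ndarray
    step: int = 0

    @property
    def finite(self) -> bool:
        return bool(np.all(np.isfinite(self.w)) and np.all(np.isfinite(self.phi_el)))


def zero_state(mesh: Mesh) -> FieldState:
    shape = (mesh.M,) * 3
    return FieldState(w=np.zeros(shape, dtype=complex),
                      phi_el=np.zeros(shape, dtype=complex))


# ---------------------------------------------------------------------------
# single-chain propagators

@dataclass
class PropagatorResult:
    """Forward propagators q(r, j) and the single-chain partition function."""

    q: list[np.ndarray]
    Q: complex


def _psi_fields(state: FieldState, mesh: Mesh, charges: Sequence[int],
                gamma_k: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """psi_z = i Gamma*w + i z Gamma*phi for each distinct charge z."""
    gw = mesh.smear(state.w, gamma_k)
    gphi = mesh.smear(state.phi_el, gamma_k)
    return {z: 1j * (gw + z * gphi) for z in set(charges)}


def propagate_chain(state: FieldState, seq: ChargedSequence, mesh: Mesh,
                    keep_all: bool = True,
                    kernels: tuple[np.ndarray, np.ndarray] | None = None) -> PropagatorResult:
    """Iterate the discrete-chain transfer step and return q(r, j), Q.

    q(r, 0) = exp(-psi(r, z_0)); each subsequent monomer applies the
    normalized Gaussian bond kernel spectrally and multiplies by
    exp(-psi(r, z_j)). Q = (1/V) int q(r, N-1) dr; with zero fields Q = 1
    exactly.
    """
    bond_k, gamma_k = kernels if kernels is not None else (None, None)
    # divergence is detected from the finiteness of Q below; transient
    # overflow during a blowing-up CL trajectory is expected, not an error
    with np.errstate(over="ignore", invalid="ignore"):
        psi = _psi_fields(state, mesh, seq.z, gamma_k)
        boltz = {z: np.exp(-p) for z, p in psi.items()}
        q = boltz[seq.z[0]].copy()
        qs = [q] if keep_all else []
        for j in range(1, seq.N):
            q = boltz[seq.z[j]] * mesh.convolve_bond(q, bond_k)
            if keep_all:
                qs.append(q)
        Q = complex(np.mean(q))
    if not np.isfinite(Q.real) or not np.isfinite(Q.imag):
        raise FloatingPointError("chain propagator diverged (CL instability)")
    return PropagatorResult(q=qs, Q=Q)


def _chain_density(state: FieldState, seq: ChargedSequence, mesh: Mesh,
                   number_density: float) -> tuple[np.ndarray, np.ndarray, complex]:
    """Total and charge-weighted monomer density operators of one chain type.

    rho_j(r) = (n/V Q) q(r, j) qdag(r, j) exp(+psi_j(r)); the backward
    propagator is streamed so only the forward set is stored.
    """
    psi = _psi_fields(state, mesh, seq.z)
    boltz = {z: np.exp(-p) for z, p in psi.items()}
    fwd = propagate_chain(state, seq, mesh, keep_all=True)
    N = seq.N
    dens = np.zeros_like(state.w)
    cdens = np.zeros_like(state.w)
    qd = boltz[seq.z[N - 1]].copy()
    for j in range(N - 1, -1, -1):
        if j < N - 1:
            qd = boltz[seq.z[j]] * mesh.convolve_bond(qd)
        contrib = fwd.q[j] * qd * np.exp(psi[seq.z[j]])
        dens += contrib
        cdens += seq.z[j] * contrib
    scale = number_density / fwd.Q
    return dens * scale, cdens * scale, fwd.Q


def density_operators(state: FieldState, model: FTSModel, mesh: Mesh):
    """Instantaneous total and charge density operators plus all Q values.

    Returns (rho_total, rho_charge, Q_chains, Q_plus, Q_minus); rho_total
    counts every monomer and ion (all carry excluded volume), rho_charge is
    charge-weighted. The spatial mean of rho_total equals C plus the ion
    densities as an operator identity.
    """
    rho = np.zeros_like(state.w)
    rho_c = np.zeros_like(state.w)
    Qs: list[complex] = []
    for seq, f in model.chains:
        n_over_V = model.C * f / seq.N
        d, cd, Q = _chain_density(state, seq, mesh, n_over_V)
        rho += d
        rho_c += cd
        Qs.append(Q)
    psi_ion = _psi_fields(state, mesh, (1, -1))
    Q_p = Q_m = 1.0 + 0j
    if model.c_plus > 0:
        e = np.exp(-psi_ion[1])
        Q_p = complex(np.mean(e))
        rho_ion = model.c_plus * e / Q_p
        rho += rho_ion
        rho_c += rho_ion
    if model.c_minus > 0:
        e = np.exp(-psi_ion[-1])
        Q_m = complex(np.mean(e))
        rho_ion = model.c_minus * e / Q_m
        rho += rho_ion
        rho_c -= rho_ion
    return rho, rho_c, Qs, Q_p, Q_m


# ---------------------------------------------------------------------------
# Hamiltonian, operators

def hamiltonian(state: FieldState, model: FTSModel, mesh: Mesh) -> complex:
    """Complex field Hamiltonian; exactly zero for zero fields."""
    quad_w = mesh.dV * np.sum(state.w**2) / (2.0 * model.B)
    phik = np.fft.fftn(state.phi_el) / mesh.M**3
    grad2 = mesh.V * np.sum(mesh.k2 * phik * phik[_neg_index(mesh.M)])
    quad_phi = grad2 / (2.0 * model.E) if model.E > 0 else 0.0
    logQ = 0.0 + 0j
    for seq, f in model.chains:
        n_l = model.C * f / seq.N * mesh.V
        res = propagate_chain(state, seq, mesh, keep_all=False)
        logQ += n_l * np.log(res.Q)
    psi_ion = _psi_fields(state, mesh, (1, -1))
    if model.c_plus > 0:
        logQ += model.c_plus * mesh.V * np.log(complex(np.mean(np.exp(-psi_ion[1]))))
    if model.c_minus > 0:
        logQ += model.c_minus * mesh.V * np.log(complex(np.mean(np.exp(-psi_ion[-1]))))
    return complex(quad_w + quad_phi - logQ)


def _neg_index(M: int):
    """Index arrays mapping k -> -k on the FFT grid."""
    idx = (-np.arange(M)) % M
    return np.ix_(idx, idx, idx)


def chemical_potential_op(Q: complex, C: float, phi_l: float, N_l: int) -> complex:
    """mu_l = ln(C phi_l / N_l) - ln Q_l; the ideal-gas form at Q = 1."""
    return complex(np.log(C * phi_l / N_l) - np.log(Q))


def pressure_op(state: FieldState, model: FTSModel, mesh: Mesh,
                eps: float = 1e-5) -> complex:
    """Dimensionless osmotic pressure operator Pi = -dF/dV.

    Ideal (translational) part: the total chain + ion number density. Field
    parts follow from rescaling positions at fixed field configurations: the
    w^2 term scales with V, the gradient term with V^{1/3}, and the ln Q
    terms through the volume dependence of the bond and smearing kernels,
    evaluated here by a central finite difference of ln Q on kernels with
    k^2 scaled by exp(-+ 2 eps / 3).
    """
    ideal = model.chain_number_density + model.c_plus + model.c_minus

    quad_w = mesh.dV * np.sum(state.w**2) / (2.0 * model.B)
    phik = np.fft.fftn(state.phi_el) / mesh.M**3
    grad2 = mesh.V * np.sum(mesh.k2 * phik * phik[_neg_index(mesh.M)])
    quad_phi = grad2 / (2.0 * model.E) if model.E > 0 else 0.0

    dlogQ = 0.0 + 0j
    for sgn in (+1, -1):
        scale = np.exp(-sgn * 2.0 * eps / 3.0)  # k^2 factor for ln V +- eps
        bond_k = np.exp(-mesh.k2 * scale)
        gamma_k = np.exp(-mesh.k2 * scale / 2.0)
        total = 0.0 + 0j
        for seq, f in model.chains:
            n_over_V = model.C * f / seq.N
            res = propagate_chain(state, seq, mesh, keep_all=False,
                                  kernels=(bond_k, gamma_k))
            total += n_over_V * np.log(res.Q)
        psi_ion = _psi_fields(state, mesh, (1, -1), gamma_k)
        if model.c_plus > 0:
            total += model.c_plus * np.log(complex(np.mean(np.exp(-psi_ion[1]))))
        if model.c_minus > 0:
            total += model.c_minus * np.log(complex(np.mean(np.exp(-psi_ion[-1]))))
        dlogQ += sgn * total
    dlnQ_dlnV = dlogQ / (2.0 * eps)

    return complex(ideal - quad_w / mesh.V - quad_phi / (3.0 * mesh.V) + dlnQ_dlnV)


def pressure_counterterm(model: FTSModel, mesh: Mesh) -> float:
    """Gaussian-reference counterterm for the CL average of ``pressure_op``.

    The auxiliary-field transform divides out normalized Gaussian measures
    whose widths depend on the cell volume; their volume derivative,
    M^3/(2V) for w and (M^3 - 1)/(6V) for the gauge-fixed phi, must be
    added back when averaging the pressure operator over a fluctuating
    trajectory. It exactly cancels the equipartition part of the quadratic
    operator terms. At a deterministic saddle point (no noise) the fields
    do not fluctuate and this term must be omitted.
    """
    ct = mesh.M**3 / (2.0 * mesh.V)
    if model.E > 0:
        ct += (mesh.M**3 - 1) / (6.0 * mesh.V)
    return ct


# ---------------------------------------------------------------------------
# complex Langevin dynamics

class CLDriver:
    """ETD complex-Langevin integrator for one FTSModel."""

    def __init__(self, model: FTSModel, rng: np.random.Generator | None = None):
        self.model = model
        self.mesh = Mesh(model.L, model.M)
        self.rng = rng if rng is not None else np.random.Generator(
            np.random.Philox(model.seed))
        m, mesh = model, self.mesh
        # ETD coefficients from the Gaussian part of H
        a_w = m.lambda_w / m.B
        self._decay_w = math.exp(-a_w * m.dt)
        self._gain_w = (1.0 - self._decay_w) / a_w
        a_phi = m.lambda_phi * mesh.k2 / m.E if m.E > 0 else np.zeros_like(mesh.k2)
        with np.errstate(divide="ignore", invalid="ignore"):
            decay = np.exp(-a_phi * m.dt)
            gain = np.where(a_phi > 0, (1.0 - decay) / np.where(a_phi > 0, a_phi, 1.0),
                            m.dt)
        self._decay_phi, self._gain_phi = decay, gain
        # exact Ornstein-Uhlenbeck noise amplitudes for the linear part:
        # variance (1 - exp(-2 a dt)) lambda / (a dV), -> 2 lambda dt / dV
        # as a -> 0; removes the O(dt) bias in the Gaussian fluctuations
        self._noise_std_w = math.sqrt(
            (1.0 - self._decay_w**2) * m.lambda_w / (a_w * mesh.dV))
        base = 2.0 * m.lambda_phi * m.dt / mesh.dV
        with np.errstate(divide="ignore", invalid="ignore"):
            filt = np.where(a_phi > 0,
                            (1.0 - decay**2)
                            / (np.where(a_phi > 0, a_phi, 1.0) * 2.0 * m.dt),
                            1.0)
        self._noise_std_phi = math.sqrt(base)
        self._noise_filter_phi = np.sqrt(filt)  # spectral OU correction

    def init_state(self, noise: float = 0.0) -> FieldState:
        state = zero_state(self.mesh)
        if noise > 0:
            shape = (self.mesh.M,) * 3
            state.w += noise * self.rng.standard_normal(shape)
            state.phi_el += noise * self.rng.standard_normal(shape)
        return state

    def forces(self, state: FieldState):
        """Nonlinear force parts: i Gamma*rho for w, i Gamma*rho_c for phi."""
        rho, rho_c, Qs, Q_p, Q_m = density_operators(state, self.model, self.mesh)
        f_w = 1j * self.mesh.smear(rho)
        f_phi = 1j * self.mesh.smear(rho_c)
        return f_w, f_phi, Qs, Q_p, Q_m, rho

    def step(self, state: FieldState, with_noise: bool = True) -> FieldState:
        """One ETD update of both fields (mutates and returns ``state``)."""
        m, mesh = self.model, self.mesh
        f_w, f_phi, *_ = self.forces(state)
        # w channel: uniform linear coefficient, update in real space
        state.w = self._decay_w * state.w - self._gain_w * m.lambda_w * f_w
        # phi channel: k-dependent coefficient, update spectrally
        if m.E > 0:
            phik = np.fft.fftn(state.phi_el)
            fk = np.fft.fftn(f_phi)
            phik = self._decay_phi * phik - self._gain_phi * m.lambda_phi * fk
            phik[0, 0, 0] = 0.0  # gauge: neutral box, zero-mode fixed
            state.phi_el = np.fft.ifftn(phik)
        if with_noise:
            shape = (mesh.M,) * 3
            state.w += self._noise_std_w * self.rng.standard_normal(shape)
            if m.E > 0:
                eta = self._noise_std_phi * self.rng.standard_normal(shape)
                # shape the white noise to the exact per-mode OU variance
                etak = self._noise_filter_phi * np.fft.fftn(eta)
                etak[0, 0, 0] = 0.0  # keep the gauge
                state.phi_el += np.fft.ifftn(etak).real
        state.step += 1
        if not state.finite:
            raise FloatingPointError(f"CL fields diverged at step {state.step}")
        return state


@dataclass
class CLTrajectory:
    """Sampled CL observables with automatic equilibration and block errors."""

    samples: pd.DataFrame
    model: FTSModel
    equilibration: int = 0
    diverged_at: int | None = None
    density_mean: np.ndarray | None = None

    @property
    def production(self) -> pd.DataFrame:
        return self.samples.iloc[self.equilibration:]

    def mean_se(self, column: str, n_blocks: int = 10) -> tuple[float, float]:
        """Block-averaged mean and standard error of a sampled observable."""
        x = self.production[column].to_numpy()
        if len(x) < n_blocks:
            raise ValueError("too few post-equilibration samples for blocking")
        usable = len(x) - len(x) % n_blocks
        blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
        return float(blocks.mean()), float(blocks.std(ddof=1) / math.sqrt(n_blocks))


def _auto_equilibration(series: np.ndarray, minimum_frac: float = 0.2) -> int:
    """Marginal-standard-error cutoff, at least ``minimum_frac`` discarded."""
    n = len(series)
    lo = int(minimum_frac * n)
    candidates = np.unique(np.linspace(lo, n // 2, 7, dtype=int))
    best, best_mse = lo, np.inf
    for c in candidates:
        tail = series[c:]
        if len(tail) < 4:
            continue
        mse = tail.var(ddof=1) / len(tail)
        if mse < best_mse:
            best, best_mse = int(c), mse
    return best


def run_cl(model: FTSModel, steps: int, seed: int | None = None,
           sample_every: int = 10, pressure_every: int | None = None,
           collect_density: bool = False, max_restarts: int = 3,
           init_noise: float = 0.0) -> CLTrajectory:
    """Integrate the CL equations and sample operators along the way.

    Samples (every ``sample_every`` steps): H, per-chain ln Q and mu, the
    total chemical potential (charge-neutral combination sum nu_l mu_l),
    the spatial mean density, and the osmotic pressure (every
    ``pressure_every`` samples; defaults to every sample). Trajectories are
    bitwise reproducible for a fixed seed. Divergent runs are restarted
    with a perturbed substream; if more than half the attempts diverge a
    stability diagnosis (reduce dt) is raised.
    """
    if seed is None:
        seed = model.seed
    if pressure_every is None:
        pressure_every = 1
    attempts = 0
    diverged = 0
    last_fail = None
    while attempts < max_restarts:
        attempts += 1
        rng = np.random.Generator(np.random.Philox(key=seed + 7919 * (attempts - 1)))
        driver = CLDriver(model, rng)
        state = driver.init_state(noise=init_noise)
        rows = []
        dens_acc = None
        n_acc = 0
        try:
            for t in range(1, steps + 1):
                driver.step(state)
                if t % sample_every == 0:
                    rho, rho_c, Qs, Q_p, Q_m = density_operators(
                        state, model, driver.mesh)
                    row = {"step": t}
                    mu_tot = 0.0 + 0j
                    for (seq, f), Q, nu in zip(model.chains, Qs, model.nu):
                        mu = chemical_potential_op(Q, model.C, f, seq.N)
                        name = seq.name or f"chain{len(row)}"
                        row[f"mu_{name}_re"] = mu.real
                        row[f"mu_{name}_im"] = mu.imag
                        mu_tot += nu * mu
                    row["mu_re"], row["mu_im"] = mu_tot.real, mu_tot.imag
                    dens = complex(np.mean(rho))
                    row["density_re"], row["density_im"] = dens.real, dens.imag
                    H = hamiltonian(state, model, driver.mesh)
                    row["H_re"], row["H_im"] = H.real, H.imag
                    if (len(rows) % pressure_every) == 0:
                        Pi = pressure_op(state, model, driver.mesh)
                        Pi += pressure_counterterm(model, driver.mesh)
                        row["Pi_re"], row["Pi_im"] = Pi.real, Pi.imag
                    rows.append(row)
                    if collect_density and t > steps // 2:
                        dens_acc = rho.real if dens_acc is None else dens_acc + rho.real
                        n_acc += 1
        except FloatingPointError as err:
            diverged += 1
            last_fail = (state.step, err)
            continue
        df = pd.DataFrame(rows)
        if "Pi_re" in df.columns:
            df["Pi_re"] = df["Pi_re"].ffill()
            df["Pi_im"] = df["Pi_im"].ffill()
        eq = _auto_equilibration(df["H_re"].to_numpy())
        return CLTrajectory(
            samples=df, model=model, equilibration=eq,
            density_mean=None if dens_acc is None else dens_acc / max(n_acc, 1),
        )
    raise RuntimeError(
        f"CL unstable: {diverged}/{attempts} trajectories diverged "
        f"(last at step {last_fail[0]}); consider a smaller dt than {model.dt}"
    )


def low_k_structure_factor(rho: np.ndarray, mesh: Mesh) -> float:
    """Density structure factor averaged over the lowest nonzero-k shell.

    S(k) = V <rho_k rho_{-k}> for the (complex) density operator; values
    well above the mean density signal macroscopic segregation, the
    hallmark of phase separation in a periodic box.
    """
    rk = np.fft.fftn(rho) / mesh.M**3
    k2 = mesh.k2
    kmin = np.partition(np.unique(k2.ravel()), 1)[1]
    mask = np.isclose(k2, kmin)
    return float((mesh.V * np.mean((rk * rk[_neg_index(mesh.M)])[mask])).real)


# ---------------------------------------------------------------------------
# phase coexistence from (C, mu, Pi) branches

@dataclass(frozen=True)
class CoexistencePoint:
    """Coexisting dilute/dense monomer densities and the common mu, Pi."""

    rho_I: float
    rho_II: float
    mu_star: float
    Pi_star: float

    def __post_init__(self) -> None:
        if not self.rho_I < self.rho_II:
            raise ValueError("dilute density must be below the dense density")


def find_coexistence(C: np.ndarray, mu: np.ndarray, Pi: np.ndarray,
                     mu_err: np.ndarray | None = None,
                     Pi_err: np.ndarray | None = None) -> CoexistencePoint | None:
    """Locate the Pi-mu crossing of the dilute and concentrated branches.

    Samples are sorted by density and classified by the van-der-Waals loop
    of mu(C): the dilute branch ends at the first local maximum of mu, the
    concentrated branch starts at the last local minimum; the unstable
    branch between them is discarded. Each stable branch's Pi(mu) is
    interpolated and the crossing mu* gives (rho_I, rho_II) by inverse
    interpolation of rho(mu). Returns None (single phase or unsampled gap)
    when mu is monotone or the branches do not cross.
    """
    order = np.argsort(C)
    C, mu, Pi = np.asarray(C, float)[order], np.asarray(mu, float)[order], \
        np.asarray(Pi, float)[order]
    d = np.diff(mu)
    decreasing = np.nonzero(d < 0)[0]
    if len(decreasing) == 0:
        return None  # monotone: single branch
    i_end = int(decreasing[0])           # last index of the dilute branch
    i_start = int(decreasing[-1]) + 1    # first index of the concentrated branch
    dil = slice(0, i_end + 1)
    con = slice(i_start, len(C))
    if (i_end + 1) < 3 or (len(C) - i_start) < 3:
        raise ValueError("need at least 3 samples on each stable branch")
    mu_d, Pi_d, C_d = mu[dil], Pi[dil], C[dil]
    mu_c, Pi_c, C_c = mu[con], Pi[con], C[con]
    lo = max(mu_d.min(), mu_c.min())
    hi = min(mu_d.max(), mu_c.max())
    if lo >= hi:
        return None  # branches do not overlap in mu: gap in the sampling

    from scipy.interpolate import interp1d
    from scipy.optimize import brentq

    f_d = interp1d(mu_d, Pi_d, kind="linear")
    f_c = interp1d(mu_c, Pi_c, kind="linear")

    def gap(m: float) -> float:
        return float(f_d(m) - f_c(m))

    grid = np.linspace(lo, hi, 200)
    vals = np.array([gap(m) for m in grid])
    idx = np.nonzero(np.sign(vals[1:]) != np.sign(vals[:-1]))[0]
    if len(idx) == 0:
        return None
    mu_star = brentq(gap, grid[idx[0]], grid[idx[0] + 1], xtol=1e-12)
    Pi_star = float(f_d(mu_star))
    rho_I = float(interp1d(mu_d, C_d, kind="linear")(mu_star))
    rho_II = float(interp1d(mu_c, C_c, kind="linear")(mu_star))
    return CoexistencePoint(rho_I=rho_I, rho_II=rho_II,
                            mu_star=float(mu_star), Pi_star=Pi_star)


# ---------------------------------------------------------------------------
# checkpoints

def save_state(path, state: FieldState, model: FTSModel) -> None:
    """HDF5 checkpoint of the field configuration."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("w", data=state.w)
        fh.create_dataset("phi_el", data=state.phi_el)
        fh.attrs["step"] = state.step
        fh.attrs["B"], fh.attrs["E"], fh.attrs["C"] = model.B, model.E, model.C
        fh.attrs["L"], fh.attrs["M"], fh.attrs["dt"] = model.L, model.M, model.dt


def load_state(path) -> FieldState:
    import h5py

    with h5py.File(path, "r") as fh:
        return FieldState(w=fh["w"][...], phi_el=fh["phi_el"][...],
                          step=int(fh.attrs["step"]))
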