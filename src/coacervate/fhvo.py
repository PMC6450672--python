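"""Flory-Huggins-Voorn-Overbeek lattice model of complex coacervation.

The five-species mixture (polycation tau, polyanion RNA, Na+, Cl-, water)
is mapped onto a lattice with free energy of mixing per site

    f = sum_i (phi_i / N_i) ln phi_i  -  alpha [sum_i sigma_i phi_i]^{3/2}
        + sum_{i<j} chi_ij phi_i phi_j

with the Debye-Hueckel electrostatic strength

    alpha(T) = (2/3) sqrt(pi) (l_B / l_w)^{3/2}

and a single adjustable chi acting on the polymer-water pairs. Tau and RNA
are mixed at a fixed 1:1 charge ratio and the salt is assumed to partition
equally between phases, so at fixed salt fraction and temperature the free
energy is a function of the total polymer volume fraction alone. Coexisting
compositions are the common-tangent (bitangent) points of f(phi_polymer).

Fitting proceeds in two stages: a scalar chi is solved for at each measured
cloud point so that the dilute binodal branch passes through the measured
composition, and the resulting (T_cp, chi) points are regressed against
chi(T) = A + B/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import constants
from scipy.optimize import brentq, minimize_scalar, root

from .sequences import SpeciesSpec
from .thermo import EPS_R_WATER, bjerrum_length

#: molarity of pure water, mol/L
C_WATER = 55.56

#: ammonium acetate background buffer contributing to the monovalent salt, mM
BUFFER_SALT_MM = 20.0


def lattice_length(cw: float = C_WATER) -> float:
    """Lattice site length l_w = (1e-3 m^3 / (c_w N_A))^{1/3}, meters."""
    return (1e-3 / (cw * constants.N_A)) ** (1.0 / 3.0)


def electrostatic_strength(T: float, lw: float | None = None,
                           eps_r: float = EPS_R_WATER) -> float:
    """Debye-Hueckel prefactor alpha = (2/3) sqrt(pi) (l_B/l_w)^{3/2}."""
    if lw is None:
        lw = lattice_length()
    lb = bjerrum_length(T, eps_r)
    return (2.0 / 3.0) * np.sqrt(np.pi) * (lb / lw) ** 1.5


# ---------------------------------------------------------------------------
# mixture parameterization

@dataclass(frozen=True)
class MixtureParams:
    """Composition rules of the charge-matched tau-RNA-salt-water mixture.

    Defaults follow the experimental system: the His-tagged tau construct
    with N_tau = 207 lattice sites and net charge +11, polyU RNA of 900 kDa
    (N_rna = 2941 nucleotides), and a 20 mM buffer-salt background. The RNA
    volume fraction tracks the tau charge ([RNA nucleotides] = q_tau [tau]),
    so the polymer is split tau:RNA = N_tau : q_tau by volume.
    """

    N_tau: int = 207
    q_tau: int = 11
    N_rna: int = 2941
    cw: float = C_WATER
    buffer_mM: float = BUFFER_SALT_MM
    eps_r: float = EPS_R_WATER

    @property
    def sigma_tau(self) -> float:
        return self.q_tau / self.N_tau

    @property
    def r_tau(self) -> float:
        """Tau share of the polymer volume fraction."""
        return self.N_tau / (self.N_tau + self.q_tau)

    @property
    def sites_per_tau(self) -> int:
        """Lattice sites of polymer per tau molecule (tau + matched RNA)."""
        return self.N_tau + self.q_tau

    @property
    def charge_coef(self) -> float:
        """d(sum sigma_i phi_i)/d(phi_polymer) of the polymer species."""
        r = self.r_tau
        return r * self.sigma_tau + (1.0 - r) * 1.0

    def phi_polymer(self, tau_uM: float) -> float:
        return tau_uM * 1e-6 * self.sites_per_tau / self.cw

    def phi_salt(self, nacl_mM: float) -> float:
        return (nacl_mM + self.buffer_mM) * 1e-3 / self.cw

    def tau_uM(self, phi_polymer: float) -> float:
        return phi_polymer * self.cw / self.sites_per_tau * 1e6

    def nacl_mM(self, phi_salt: float) -> float:
        return phi_salt * self.cw * 1e3 - self.buffer_mM


DEFAULT_PARAMS = MixtureParams()


@dataclass(frozen=True)
class LatticeSystem:
    """A fully specified five-species lattice state."""

    species: tuple[SpeciesSpec, ...]
    phi: np.ndarray
    T: float
    chi: np.ndarray          # symmetric pairwise chi_ij matrix
    alpha: float
    lw: float
    cw: float = C_WATER

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)
        chi = np.asarray(self.chi, dtype=float)
        object.__setattr__(self, "chi", chi)
        n = len(self.species)
        if phi.shape != (n,):
            raise ValueError("one volume fraction per species required")
        if chi.shape != (n, n) or not np.allclose(chi, chi.T):
            raise ValueError("chi must be a symmetric (n, n) matrix")
        if np.any(phi < 0):
            raise ValueError("volume fractions must be non-negative")
        if abs(phi.sum() - 1.0) > 1e-12:
            raise ValueError(f"volume fractions must sum to 1, got {phi.sum()!r}")


def _chi_matrix(chi: float, species: Sequence[SpeciesSpec]) -> np.ndarray:
    """Single-chi convention: chi on each polymer-water pair, else zero."""
    n = len(species)
    mat = np.zeros((n, n))
    for i, si in enumerate(species):
        for j, sj in enumerate(species):
            roles = {si.role, sj.role}
            if "solvent" in roles and ({"polycation", "polyanion"} & roles):
                mat[i, j] = chi
    return mat


def composition_from_conditions(tau_uM: float, nacl_mM: float,
                                T: float = 293.15, chi: float = 0.0,
                                params: MixtureParams = DEFAULT_PARAMS) -> LatticeSystem:
    """Build the lattice state from experimental [tau] (uM) and [NaCl] (mM).

    phi_tau = [tau] N_tau / c_w, phi_RNA = [tau] q_tau / c_w (1:1 charge
    matching), phi_salt = ([NaCl] + buffer) / c_w split equally between the
    two ions, phi_water closes the sum to one.
    """
    if tau_uM < 0 or nacl_mM < 0:
        raise ValueError("concentrations must be >= 0")
    c_tau = tau_uM * 1e-6
    phi_tau = c_tau * params.N_tau / params.cw
    phi_rna = c_tau * params.q_tau / params.cw
    phi_salt = params.phi_salt(nacl_mM)
    phi_w = 1.0 - phi_tau - phi_rna - phi_salt
    if phi_w <= 0:
        raise ValueError("unphysical concentrations: no room left for water")
    species = (
        SpeciesSpec("tau", "polycation", params.N_tau, params.sigma_tau),
        SpeciesSpec("RNA", "polyanion", params.N_rna, 1.0),
        SpeciesSpec("Na+", "cation", 1, 1.0),
        SpeciesSpec("Cl-", "anion", 1, 1.0),
        SpeciesSpec("water", "solvent", 1, 0.0),
    )
    phi = np.array([phi_tau, phi_rna, phi_salt / 2, phi_salt / 2, phi_w])
    lw = lattice_length(params.cw)
    return LatticeSystem(
        species=species, phi=phi, T=T, chi=_chi_matrix(chi, species),
        alpha=electrostatic_strength(T, lw, params.eps_r), lw=lw, cw=params.cw,
    )


def free_energy_per_site(sys: LatticeSystem) -> float:
    """Dimensionless mixing free energy per lattice site (Delta G_m / M kT).

    Species with phi_i = 0 contribute nothing to the entropy term.
    """
    phi = sys.phi
    N = np.array([s.N for s in sys.species], dtype=float)
    sigma = np.array([s.sigma for s in sys.species], dtype=float)
    mask = phi > 0
    entropy = np.sum(phi[mask] / N[mask] * np.log(phi[mask]))
    electro = -sys.alpha * np.sum(sigma * phi) ** 1.5
    pairs = 0.0
    n = len(phi)
    for i in range(n):
        for j in range(i + 1, n):
            pairs += sys.chi[i, j] * phi[i] * phi[j]
    return float(entropy + electro + pairs)


# ---------------------------------------------------------------------------
# reduced one-variable free energy f(phi_polymer) at fixed salt, T, chi

@dataclass(frozen=True)
class ReducedFreeEnergy:
    """f(phi_polymer) and derivatives at fixed (phi_salt, chi, alpha).

    ``components`` lists the polymer species as (N_i, sigma_i, r_i) with
    volume-fraction shares r_i summing to one. The single chi acts between
    the total polymer and water. Salt enters as two monovalent ions of
    phi_salt/2 each (their entropy is constant in phi but kept for
    completeness of f).
    """

    components: tuple[tuple[float, float, float], ...]
    phi_salt: float
    chi: float
    alpha: float

    @property
    def s_coef(self) -> float:
        return sum(r * sigma for N, sigma, r in self.components)

    @property
    def phi_max(self) -> float:
        return 1.0 - self.phi_salt

    def _salt_entropy(self) -> float:
        ps = self.phi_salt
        return ps * np.log(ps / 2.0) if ps > 0 else 0.0

    def f(self, phi):
        phi = np.asarray(phi, dtype=float)
        pw = 1.0 - phi - self.phi_salt
        out = np.where(pw > 0, pw * np.log(np.where(pw > 0, pw, 1.0)), np.inf)
        for N, sigma, r in self.components:
            p = r * phi
            out = out + np.where(p > 0, p / N * np.log(np.where(p > 0, p, 1.0)), 0.0)
        out = out + self._salt_entropy()
        if self.alpha != 0:
            ionic = self.s_coef * phi + self.phi_salt
            out = out - self.alpha * np.abs(ionic) ** 1.5
        out = out + self.chi * phi * pw
        return out if out.ndim else float(out)

    def df(self, phi):
        phi = np.asarray(phi, dtype=float)
        pw = 1.0 - phi - self.phi_salt
        out = -(np.log(pw) + 1.0)
        for N, sigma, r in self.components:
            out = out + r / N * (np.log(r * phi) + 1.0)
        s = self.s_coef
        if self.alpha != 0 and s != 0:
            out = out - 1.5 * self.alpha * s * np.sqrt(s * phi + self.phi_salt)
        out = out + self.chi * (1.0 - 2.0 * phi - self.phi_salt)
        return out if out.ndim else float(out)

    def d2f(self, phi):
        phi = np.asarray(phi, dtype=float)
        pw = 1.0 - phi - self.phi_salt
        coef = sum(r / N for N, sigma, r in self.components)
        s = self.s_coef
        out = coef / phi + 1.0 / pw
        if self.alpha != 0 and s != 0:
            out = out - 0.75 * self.alpha * s**2 / np.sqrt(s * phi + self.phi_salt)
        out = out - 2.0 * self.chi
        return out if out.ndim else float(out)

    def intercept(self, phi):
        """Tangent intercept f(phi) - phi f'(phi)."""
        return self.f(phi) - phi * self.df(phi)


def reduced_free_energy(phi_salt: float, T: float, chi: float,
                        params: MixtureParams = DEFAULT_PARAMS) -> ReducedFreeEnergy:
    """Reduced f(phi_polymer) for the experimental tau-RNA mixture."""
    r = params.r_tau
    comps = ((float(params.N_tau), params.sigma_tau, r),
             (float(params.N_rna), 1.0, 1.0 - r))
    alpha = electrostatic_strength(T, lattice_length(params.cw), params.eps_r)
    return ReducedFreeEnergy(components=comps, phi_salt=phi_salt,
                             chi=chi, alpha=alpha)


def neutral_fh(N: float, chi: float) -> ReducedFreeEnergy:
    """Plain neutral polymer-solvent Flory-Huggins f(phi) (alpha = 0)."""
    return ReducedFreeEnergy(components=((float(N), 0.0, 1.0),),
                             phi_salt=0.0, chi=chi, alpha=0.0)


def fh_critical_point(N: float) -> tuple[float, float]:
    """Closed-form neutral FH critical point (chi_c, phi_c)."""
    return 0.5 * (1.0 + 1.0 / np.sqrt(N)) ** 2, 1.0 / (1.0 + np.sqrt(N))


# ---------------------------------------------------------------------------
# bitangent construction

@dataclass(frozen=True)
class BinodalPair:
    """Coexisting dilute/dense polymer volume fractions at fixed salt, T."""

    phi1: float
    phi2: float
    phi_salt: float
    T: float
    chi: float
    method: str = "newton"

    def __post_init__(self) -> None:
        if not self.phi1 <= self.phi2:
            raise ValueError("phi1 must not exceed phi2")

    @property
    def width(self) -> float:
        return self.phi2 - self.phi1

    @property
    def degenerate(self) -> bool:
        return self.phi2 <= self.phi1 * (1 + 1e-9)


_PHI_FLOOR = 1e-12


def _phi_grid(fe: ReducedFreeEnergy, n: int = 400) -> np.ndarray:
    """Log-spaced grid resolving the steep dilute branch down to 1e-12."""
    hi = fe.phi_max * (1.0 - 1e-9)
    return np.geomspace(_PHI_FLOOR, hi, n)


def spinodal_interval(fe: ReducedFreeEnergy) -> tuple[float, float] | None:
    """(phi_lo, phi_hi) where f'' < 0, or None if f is locally stable."""
    grid = _phi_grid(fe, 600)
    vals = fe.d2f(grid)
    neg = np.nonzero(vals < 0)[0]
    if len(neg) == 0:
        return None
    roots = []
    sign_change = np.nonzero(np.sign(vals[1:]) != np.sign(vals[:-1]))[0]
    for i in sign_change:
        roots.append(brentq(fe.d2f, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-14))
    if len(roots) == 0:
        # f'' < 0 down to the grid edge (strong electrostatics): use edges
        roots = [grid[neg[0]], grid[neg[-1]]]
    if len(roots) == 1:
        roots = [grid[neg[0]] if neg[0] == 0 else roots[0], roots[0]]
    return float(min(roots)), float(max(roots))


def bitangent_hull(fe: ReducedFreeEnergy, n_grid: int = 2000,
                   n_refine: int = 60) -> BinodalPair | None:
    """Common tangent by lower-convex-envelope / tangent iteration.

    Independent of the Newton path: locate the hull chord on a dense grid,
    then iterate the tangent construction (minimize f - mu*phi on each side
    of the chord and update the slope) with bounded scalar minimization.
    """
    grid = _phi_grid(fe, n_grid)
    fvals = fe.f(grid)
    # lower convex hull by monotone chain on (phi, f)
    hull: list[int] = []
    for i in range(len(grid)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = ((grid[i2] - grid[i1]) * (fvals[i] - fvals[i1])
                     - (fvals[i2] - fvals[i1]) * (grid[i] - grid[i1]))
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    gaps = [(hull[k + 1] - hull[k], k) for k in range(len(hull) - 1)]
    gap, k = max(gaps)
    if gap <= 1:
        return None  # envelope follows the grid: convex, single phase
    a, b = hull[k], hull[k + 1]
    lo, hi = grid[a], grid[b]

    phi1, phi2 = lo, hi
    for _ in range(n_refine):
        mu = (fe.f(phi2) - fe.f(phi1)) / (phi2 - phi1)
        mid = np.sqrt(phi1 * phi2)

        def tilted(p, mu=mu):
            return fe.f(p) - mu * p

        r1 = minimize_scalar(tilted, bounds=(_PHI_FLOOR, mid), method="bounded",
                             options={"xatol": 1e-16})
        r2 = minimize_scalar(tilted, bounds=(mid, fe.phi_max * (1 - 1e-9)),
                             method="bounded", options={"xatol": 1e-14})
        new1, new2 = float(r1.x), float(r2.x)
        if abs(new1 - phi1) < 1e-15 and abs(new2 - phi2) < 1e-13:
            phi1, phi2 = new1, new2
            break
        phi1, phi2 = new1, new2
    if phi2 - phi1 < 1e-10:
        return None
    return BinodalPair(phi1=phi1, phi2=phi2, phi_salt=fe.phi_salt, T=np.nan,
                       chi=fe.chi, method="hull")


def bitangent(fe: ReducedFreeEnergy, T: float = np.nan) -> BinodalPair | None:
    """Coexisting compositions of f(phi), or None in the single-phase region.

    A damped Newton iteration in (ln phi1, ln phi2) solves the equal-slope /
    equal-intercept system, seeded around the spinodal interval; on failure
    the convex-hull construction is used and the pair is labeled
    ``method='hull'``. A spinodal that has collapsed to a point (critical
    state) returns a degenerate pair.
    """
    sp = spinodal_interval(fe)
    if sp is None:
        # detect a grazing critical point: min f'' == 0 within tolerance
        grid = _phi_grid(fe, 600)
        vals = fe.d2f(grid)
        i = int(np.argmin(vals))
        scale = abs(fe.d2f(grid[i]) - 2 * fe.chi) + 1.0 / grid[i]
        if vals[i] < 1e-7 * scale:
            res = minimize_scalar(fe.d2f, bounds=(grid[max(i - 1, 0)],
                                                  grid[min(i + 1, len(grid) - 1)]),
                                  method="bounded", options={"xatol": 1e-14})
            p = float(res.x)
            return BinodalPair(phi1=p, phi2=p, phi_salt=fe.phi_salt, T=T,
                               chi=fe.chi, method="critical")
        return None
    sp_lo, sp_hi = sp
    if sp_hi <= sp_lo * (1 + 1e-9):
        p = 0.5 * (sp_lo + sp_hi)
        return BinodalPair(phi1=p, phi2=p, phi_salt=fe.phi_salt, T=T,
                           chi=fe.chi, method="critical")

    def system(u: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            p1, p2 = np.exp(u)
            return np.array([
                fe.df(p1) - fe.df(p2),
                fe.intercept(p1) - fe.intercept(p2),
            ])

    def jac(u: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            p1, p2 = np.exp(u)
            d2_1, d2_2 = fe.d2f(p1), fe.d2f(p2)
            return np.array([
                [p1 * d2_1, -p2 * d2_2],
                [-p1**2 * d2_1, p2**2 * d2_2],
            ])

    seeds = [
        (sp_lo * s1, min(sp_hi * s2, fe.phi_max * (1 - 1e-6)))
        for s1, s2 in ((0.3, 3.0), (0.1, 1.5), (0.5, 1.2), (0.01, 10.0),
                       (1e-3, 30.0), (0.9, 1.1))
    ]
    solutions: list[tuple[float, float]] = []
    for p1_0, p2_0 in seeds:
        sol = root(system, np.log([p1_0, p2_0]), jac=jac, method="hybr",
                   options={"xtol": 1e-13})
        if not sol.success:
            continue
        p1, p2 = np.exp(sol.x)
        if not (p1 < sp_lo and sp_hi < p2 < fe.phi_max):
            continue
        if max(abs(v) for v in system(sol.x)) > 1e-8 * (1 + abs(fe.df(p1))):
            continue
        solutions.append((float(p1), float(p2)))
    if solutions:
        # tie-break between distinct bitangents: lowest common-tangent energy
        best = min(solutions, key=lambda s: fe.intercept(s[0]))
        return BinodalPair(phi1=best[0], phi2=best[1], phi_salt=fe.phi_salt,
                           T=T, chi=fe.chi, method="newton")
    pair = bitangent_hull(fe)
    if pair is None:
        return None
    return BinodalPair(phi1=pair.phi1, phi2=pair.phi2, phi_salt=fe.phi_salt,
                       T=T, chi=fe.chi, method="hull")


# ---------------------------------------------------------------------------
# chi fitting

@dataclass(frozen=True)
class ChiLaw:
    """chi(T) = A + B/T with the regression goodness of fit."""

    A: float
    B: float
    r_squared: float = np.nan
    n_points: int = 0

    def __call__(self, T):
        return self.A + self.B / np.asarray(T, dtype=float)

    @property
    def lcst_like(self) -> bool:
        """B < 0 means chi grows with T: heat-induced demixing (LCST)."""
        return self.B < 0


def fit_chi_point(tau_uM: float, nacl_mM: float, T_cp: float,
                  params: MixtureParams = DEFAULT_PARAMS,
                  tol: float = 1e-8) -> float:
    """Scalar chi placing the dilute binodal branch on the measured point.

    With the dilute composition pinned at the experimental polymer fraction
    phi1*, the equal-intercept condition is linear in chi, which reduces the
    problem to a one-dimensional root search in the dense-branch fraction
    phi2; the returned chi is verified by recomputing the full bitangent.
    """
    phi1 = params.phi_polymer(tau_uM)
    phi_salt = params.phi_salt(nacl_mM)
    if phi1 <= 0:
        raise ValueError("tau concentration must be positive")
    base = reduced_free_energy(phi_salt, T_cp, 0.0, params)  # chi = 0 parts

    def chi_of(phi2: float) -> float:
        c1 = base.intercept(phi1)
        c2 = base.intercept(phi2)
        denom = phi1**2 - phi2**2
        return (c2 - c1) / denom

    def h(phi2: float) -> float:
        chi = chi_of(phi2)
        return (base.df(phi1) - base.df(phi2)) + chi * 2.0 * (phi2 - phi1)

    lo = phi1 * 5.0
    hi = (1.0 - phi_salt) * (1.0 - 1e-6)
    grid = np.geomspace(lo, hi, 200)
    vals = np.array([h(g) for g in grid])
    idx = np.nonzero(np.sign(vals[1:]) != np.sign(vals[:-1]))[0]
    if len(idx) == 0:
        raise RuntimeError(
            f"no chi places ({tau_uM} uM, {nacl_mM} mM) on a binodal at "
            f"{T_cp} K; h spans [{vals.min():.3g}, {vals.max():.3g}] "
            f"over phi2 in [{lo:.3g}, {hi:.3g}]"
        )
    candidates = []
    for i in idx:
        phi2 = brentq(h, grid[i], grid[i + 1], xtol=1e-300, rtol=8.9e-16)
        candidates.append((chi_of(phi2), phi2))
    # keep the physically meaningful solution: dense branch above the dilute
    chi, phi2 = min(candidates, key=lambda c: c[0])

    fe = reduced_free_energy(phi_salt, T_cp, chi, params)
    pair = bitangent(fe, T_cp)
    if pair is None or abs(pair.phi1 - phi1) > tol * max(phi1, 1e-6) * 1e2:
        # fall back to a bracketed search on chi against the full bitangent
        chi = _fit_chi_bracketed(phi1, phi_salt, T_cp, params, tol)
    return float(chi)


def _fit_chi_bracketed(phi1_target: float, phi_salt: float, T: float,
                       params: MixtureParams, tol: float) -> float:
    def g(chi: float) -> float:
        fe = reduced_free_energy(phi_salt, T, chi, params)
        pair = bitangent(fe, T)
        if pair is None or pair.degenerate:
            return -phi1_target  # no coexistence: dilute branch "above" target
        return np.log(pair.phi1 / phi1_target)

    lo, hi = 0.0, 2.0
    grid = np.linspace(lo, hi, 41)
    vals = [g(c) for c in grid]
    for i in range(len(grid) - 1):
        if np.sign(vals[i]) != np.sign(vals[i + 1]) and vals[i] != -phi1_target:
            return brentq(g, grid[i], grid[i + 1], xtol=tol)
    raise RuntimeError(
        f"no chi in [{lo}, {hi}] produces coexistence through the point "
        f"(phi1={phi1_target:.3g}, phi_salt={phi_salt:.3g}, T={T:.4g} K)"
    )


def fit_chi_law(points: Sequence[tuple[float, float]]) -> ChiLaw:
    """Least-squares regression of chi on 1/T: chi = A + B/T.

    ``points`` are (T_cp in K, chi) pairs; at least three are required.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 (T, chi) points to fit chi(T)")
    T = np.array([p[0] for p in points], dtype=float)
    chi = np.array([p[1] for p in points], dtype=float)
    X = np.column_stack([np.ones_like(T), 1.0 / T])
    coef, *_ = np.linalg.lstsq(X, chi, rcond=None)
    pred = X @ coef
    ss_res = float(np.sum((chi - pred) ** 2))
    ss_tot = float(np.sum((chi - chi.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ChiLaw(A=float(coef[0]), B=float(coef[1]), r_squared=r2,
                  n_points=len(points))


# ---------------------------------------------------------------------------
# binodal curves in experimental units

def chi_required(tau_uM: float, nacl_mM: float, T: float,
                 params: MixtureParams = DEFAULT_PARAMS) -> float:
    """chi that puts the composition on the dilute binodal at temperature T."""
    return fit_chi_point(tau_uM, nacl_mM, T, params)


def cloud_point_temperature(tau_uM: float, nacl_mM: float, chi_law: ChiLaw,
                            params: MixtureParams = DEFAULT_PARAMS,
                            T_range: tuple[float, float] = (273.0, 373.0)) -> float | None:
    """T at which a composition sits on the dilute binodal under chi(T).

    Solves chi_required(T) = chi_law(T); returns None when the composition
    never touches the two-phase region in ``T_range``.
    """
    def g(T: float) -> float:
        try:
            return chi_required(tau_uM, nacl_mM, T, params) - float(chi_law(T))
        except RuntimeError:
            return np.nan

    Ts = np.linspace(*T_range, 21)
    vals = np.array([g(t) for t in Ts])
    ok = ~np.isnan(vals)
    for i in range(len(Ts) - 1):
        if ok[i] and ok[i + 1] and np.sign(vals[i]) != np.sign(vals[i + 1]):
            return float(brentq(g, Ts[i], Ts[i + 1], xtol=1e-8))
    return None


def binodal_curve(chi_law: ChiLaw, axis: str,
                  fixed: float,
                  values: np.ndarray,
                  params: MixtureParams = DEFAULT_PARAMS,
                  T_range: tuple[float, float] = (273.0, 373.0)):
    """Dilute and dense binodal branches in experimental units.

    axis = 'tau': ``values`` are [tau] in uM at fixed [NaCl] = ``fixed`` mM;
    axis = 'nacl': ``values`` are [NaCl] in mM at fixed [tau] = ``fixed`` uM;
    axis = 'T': ``values`` are temperatures (K) at fixed ([tau], [NaCl]) --
    ``fixed`` is then a (tau_uM, nacl_mM) tuple and the returned rows carry
    the coexisting polymer fractions.

    Returns a pandas DataFrame; grid points outside the two-phase window get
    NaN rather than a fabricated value.
    """
    import pandas as pd

    rows = []
    if axis in ("tau", "nacl"):
        for v in np.asarray(values, dtype=float):
            tau_uM, nacl_mM = (v, fixed) if axis == "tau" else (fixed, v)
            T_cp = cloud_point_temperature(tau_uM, nacl_mM, chi_law, params, T_range)
            row = {"tau_uM": tau_uM, "nacl_mM": nacl_mM, "T_cp_K": np.nan,
                   "tau_dense_uM": np.nan}
            if T_cp is not None:
                row["T_cp_K"] = T_cp
                fe = reduced_free_energy(params.phi_salt(nacl_mM), T_cp,
                                         float(chi_law(T_cp)), params)
                pair = bitangent(fe, T_cp)
                if pair is not None:
                    row["tau_dense_uM"] = params.tau_uM(pair.phi2)
            rows.append(row)
    elif axis == "T":
        tau_uM, nacl_mM = fixed
        phi_salt = params.phi_salt(nacl_mM)
        for T in np.asarray(values, dtype=float):
            fe = reduced_free_energy(phi_salt, T, float(chi_law(T)), params)
            pair = bitangent(fe, T)
            row = {"T_K": T, "tau_dilute_uM": np.nan, "tau_dense_uM": np.nan}
            if pair is not None and not pair.degenerate:
                row["tau_dilute_uM"] = params.tau_uM(pair.phi1)
                row["tau_dense_uM"] = params.tau_uM(pair.phi2)
            rows.append(row)
    else:
        raise ValueError("axis must be 'tau', 'nacl' or 'T'")
    return pd.DataFrame(rows)
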