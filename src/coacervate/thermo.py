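"""Temperature maps between experiment and both coarse-grained models.

The experimental control variable is temperature; the lattice model sees it
through the empirical interaction parameter chi(T) = eps_s + eps_H/T, and
the field-theoretic model through the Bjerrum length l_B(T) ~ 1/T and a
temperature-dependent excluded volume v(T) = -v0 (1 - theta/T) appropriate
for LCST (heat-induced demixing) behavior. The two parameterizations are
linked by the second-order virial relation v = b^3 (1 - 2 chi), which lets
either track be decomposed into a non-ionic excess enthalpy and a
noncombinatoric entropy per mole of monomer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

#: dielectric constant of water used throughout, treated as T-independent
EPS_R_WATER = 80.0

#: statistical segment length, m (one amino acid ~ Calpha-Calpha distance)
SEGMENT_LENGTH = 4.0e-10


def bjerrum_length(T: float, eps_r: float = EPS_R_WATER) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps_0 eps_r k_B T), in meters.

    The distance at which the Coulomb energy between two unit charges
    equals the thermal energy. ~0.70 nm in water at 300 K.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    e, eps0, kB = constants.e, constants.epsilon_0, constants.k
    out = e**2 / (4 * np.pi * eps0 * eps_r * kB * T)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TemperatureMap:
    """Map from temperature to the FTS model parameters (l_B, v).

    Parameters
    ----------
    b : segment length, m (default 4 A).
    eps_r : dielectric constant (default 80, T-independent).
    v0 : excluded-volume magnitude in units of b^3 (default 0.25).
    theta : theta temperature, K (default 309); v(theta) = 0 exactly and
        the solvent turns poor (v < 0) above it.
    """

    b: float = SEGMENT_LENGTH
    eps_r: float = EPS_R_WATER
    v0: float = 0.25
    theta: float = 309.0

    def bjerrum(self, T: float) -> float:
        """l_B(T) in meters."""
        return bjerrum_length(T, self.eps_r)

    def bjerrum_b(self, T: float) -> float:
        """l_B(T) in units of the segment length b."""
        return self.bjerrum(T) / self.b

    def excluded_volume(self, T: float) -> float:
        """v(T) = -v0 (1 - theta/T), in units of b^3."""
        T = np.asarray(T, dtype=float)
        if np.any(T <= 0):
            raise ValueError("temperature must be positive")
        out = -self.v0 * (1.0 - self.theta / T)
        return float(out) if out.ndim == 0 else out

    def chi(self, T: float) -> float:
        """chi(T) implied by v(T) through v = b^3 (1 - 2 chi)."""
        return v_to_chi(self.excluded_volume(T))

    def chi_coefficients(self) -> tuple[float, float]:
        """(eps_s, eps_H) of chi(T) = eps_s + eps_H/T implied by (v0, theta).

        Substituting v = -v0(1 - theta/T) into chi = (1 - v/b^3)/2 gives
        eps_s = (1 + v0)/2 and eps_H = -v0 theta / 2.
        """
        return (1.0 + self.v0) / 2.0, -self.v0 * self.theta / 2.0


def excluded_volume(T: float, tmap: TemperatureMap | None = None) -> float:
    """v(T) in units of b^3 (module-level convenience)."""
    return (tmap or TemperatureMap()).excluded_volume(T)


def v_to_chi(v_b3: float) -> float:
    """chi = (1 - v/b^3) / 2 from the excluded volume in b^3 units."""
    return (1.0 - v_b3) / 2.0


def chi_to_v(chi: float) -> float:
    """v/b^3 = 1 - 2 chi; exact inverse of :func:`v_to_chi`."""
    return 1.0 - 2.0 * chi


@dataclass(frozen=True)
class ThermoDecomposition:
    """Non-ionic enthalpy/entropy of phase separation per mole monomer.

    Mixing quantities follow from the noncombinatoric free energy
    DeltaG_mix = R T n chi phi_w: DeltaS_mix = -R n phi_w eps_s and
    DeltaH_mix = R n phi_w eps_H. The reported ``dH_ex`` and
    ``TdS_noncomb`` are the *phase separation* values, i.e. the negated
    mixing quantities, matching the sign convention used when quoting
    driving forces of coacervation.

    Units: kJ per mole of monomer.
    """

    eps_s: float
    eps_H: float
    T: float
    phi_w: float
    dH_ex: float
    TdS_noncomb: float

    @property
    def dG_ex(self) -> float:
        """dH_ex - TdS_noncomb = -R T phi_w chi(T), kJ/mol monomer."""
        return self.dH_ex - self.TdS_noncomb

    def summary(self) -> str:
        lines = [
            "Non-ionic thermodynamic decomposition (per mole monomer)",
            f"  chi(T) = {self.eps_s:+.4g} {self.eps_H:+.4g}/T at T = {self.T:.6g} K,"
            f" phi_w = {self.phi_w:.3f}",
            f"  Delta H^ex          = {self.dH_ex:+.3g} kJ/mol",
            f"  T Delta S^noncomb   = {self.TdS_noncomb:+.3g} kJ/mol",
            f"  Delta G^ex          = {self.dG_ex:+.3g} kJ/mol",
        ]
        return "\n".join(lines)


def decompose(eps_s: float, eps_H: float, T: float = 300.0,
              phi_w: float = 0.722) -> ThermoDecomposition:
    """Decompose chi(T) = eps_s + eps_H/T into phase-separation dH and TdS.

    Parameters
    ----------
    eps_s : dimensionless entropic coefficient of chi.
    eps_H : enthalpic coefficient of chi, K.
    T : temperature, K.
    phi_w : representative water volume fraction (default 0.722).

    Returns
    -------
    ThermoDecomposition
        With ``dH_ex = -R phi_w eps_H`` and
        ``TdS_noncomb = +R T phi_w eps_s`` in kJ/mol monomer (negated
        mixing quantities).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not 0 < phi_w <= 1:
        raise ValueError("phi_w must lie in (0, 1]")
    R = constants.R  # J / (mol K)
    dH_mix = R * phi_w * eps_H          # J/mol monomer
    TdS_mix = -R * T * phi_w * eps_s    # J/mol monomer
    return ThermoDecomposition(
        eps_s=eps_s, eps_H=eps_H, T=T, phi_w=phi_w,
        dH_ex=-dH_mix / 1e3, TdS_noncomb=-TdS_mix / 1e3,
    )
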