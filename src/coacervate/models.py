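"""Model / Results interface over the two fitting stages.

Both experimental fits follow the same two-step convention: construct a
model object holding the data and configuration, call ``fit()``, and work
with the returned results object (parameter estimates, uncertainties,
``summary()`` tables, downstream predictions). Stochastic simulation runs
(the FTS track) are deliberately not forced into this shape; they stay
simulation objects with trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cloudpoint as cp
from . import fhvo
from .thermo import ThermoDecomposition, decompose


class TurbiditySigmoidModel:
    """Sigmoid cloud-point model for one or more turbidity curves.

    Parameters
    ----------
    curves : list of TurbidityCurve (or a single curve).
    """

    def __init__(self, curves):
        if isinstance(curves, cp.TurbidityCurve):
            curves = [curves]
        if not curves:
            raise ValueError("need at least one turbidity curve")
        self.curves = list(curves)

    @classmethod
    def from_csv(cls, path) -> "TurbiditySigmoidModel":
        return cls(cp.read_curves(path))

    def fit(self) -> "CloudPointResults":
        fits = [cp.fit_cloud_point(c) for c in self.curves]
        return CloudPointResults(model=self, fits=fits)


@dataclass
class CloudPointResults:
    """Fitted cloud points with standard errors and a summary table."""

    model: TurbiditySigmoidModel
    fits: list

    @property
    def T_cp(self) -> np.ndarray:
        return np.array([f.T_cp for f in self.fits])

    @property
    def k(self) -> np.ndarray:
        return np.array([f.k for f in self.fits])

    def table(self) -> pd.DataFrame:
        return cp.fits_table(self.fits)

    def predict(self, T, which: int = 0) -> np.ndarray:
        return self.fits[which].predict(np.asarray(T, dtype=float))

    def summary(self) -> str:
        t = self.table()
        lines = ["Cloud-point sigmoid fits",
                 "=" * 62,
                 f"{'label':<12}{'branch':<9}{'T_cp (K)':>12}{'+/-':>8}"
                 f"{'k (1/K)':>10}{'+/-':>8}"]
        for _, r in t.iterrows():
            lines.append(f"{r['label'][:11]:<12}{r['branch']:<9}"
                         f"{r['T_cp_K']:>12.3f}{r['T_cp_se']:>8.3f}"
                         f"{r['k_perK']:>10.3f}{r['k_se']:>8.3f}")
        lines.append("=" * 62)
        return "\n".join(lines)


class PhaseDiagramModel:
    """FH-VO chi(T) model for a grid of measured cloud points.

    Each observation is ([tau] in uM, [NaCl] in mM, T_cp in K). ``fit()``
    extracts the chi value that places the dilute binodal branch at each
    observed cloud point and regresses chi against 1/T.
    """

    def __init__(self, tau_uM, nacl_mM, T_cp,
                 params: fhvo.MixtureParams = fhvo.DEFAULT_PARAMS):
        tau = np.asarray(tau_uM, dtype=float)
        salt = np.asarray(nacl_mM, dtype=float)
        t = np.asarray(T_cp, dtype=float)
        if not tau.shape == salt.shape == t.shape:
            raise ValueError("tau_uM, nacl_mM, T_cp must have equal shapes")
        keep = np.isfinite(t)
        self.tau_uM, self.nacl_mM, self.T_cp = tau[keep], salt[keep], t[keep]
        if len(self.T_cp) < 2:
            raise ValueError("need at least 2 finite cloud points")
        self.params = params

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       params: fhvo.MixtureParams = fhvo.DEFAULT_PARAMS):
        return cls(df["tau_uM"], df["nacl_mM"], df["T_cp"], params=params)

    def fit(self) -> "PhaseDiagramResults":
        points = []
        rows = []
        for tau, salt, t in zip(self.tau_uM, self.nacl_mM, self.T_cp):
            chi = fhvo.fit_chi_point(tau, salt, t, params=self.params)
            points.append((t, chi))
            rows.append({"tau_uM": tau, "nacl_mM": salt, "T_cp": t, "chi": chi})
        law = fhvo.fit_chi_law(points)
        return PhaseDiagramResults(model=self, chi_table=pd.DataFrame(rows),
                                   chi_law=law)


@dataclass
class PhaseDiagramResults:
    """Fitted chi(T) law with per-point chi values and derived quantities."""

    model: PhaseDiagramModel
    chi_table: pd.DataFrame
    chi_law: fhvo.ChiLaw

    @property
    def params(self) -> tuple[float, float]:
        """(A, B) of chi(T) = A + B/T."""
        return self.chi_law.A, self.chi_law.B

    def binodal(self, axis: str = "tau", fixed: float = 120.0,
                values=None) -> pd.DataFrame:
        """Dilute-branch cloud-point curve along one axis."""
        if values is None:
            values = (np.geomspace(5, 240, 25) if axis == "tau"
                      else np.linspace(30, 120, 19))
        return fhvo.binodal_curve(self.chi_law, axis=axis, fixed=fixed,
                                  values=np.asarray(values, dtype=float),
                                  params=self.model.params)

    def decompose(self, T: float = 300.0, phi_w: float = 0.722) -> ThermoDecomposition:
        """Non-ionic enthalpy/entropy split of the fitted chi law."""
        return decompose(self.chi_law.A, self.chi_law.B, T=T, phi_w=phi_w)

    def predict(self, tau_uM: float, nacl_mM: float) -> float | None:
        """Cloud point implied by the fitted law at one composition."""
        return fhvo.cloud_point_temperature(tau_uM, nacl_mM, self.chi_law,
                                            params=self.model.params)

    def summary(self) -> str:
        n = len(self.chi_table)
        A, B = self.params
        lines = [
            "FH-VO phase-diagram fit: chi(T) = A + B/T",
            "=" * 58,
            f"  observations          {n}",
            f"  A (entropic)          {A:+.4f}",
            f"  B (enthalpic, K)      {B:+.2f}",
            f"  R-squared (chi~1/T)   {self.chi_law.r_squared:.4f}",
            f"  character             "
            + ("LCST-like (B < 0)" if self.chi_law.lcst_like else "UCST-like"),
            "=" * 58,
            f"{'tau_uM':>8}{'nacl_mM':>9}{'T_cp_K':>10}{'chi':>10}",
        ]
        for _, r in self.chi_table.iterrows():
            lines.append(f"{r['tau_uM']:>8.1f}{r['nacl_mM']:>9.1f}"
                         f"{r['T_cp']:>10.2f}{r['chi']:>10.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)
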