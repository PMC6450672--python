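"""Cloud-point extraction from turbidity-temperature curves.

A heated tau-RNA mixture turns turbid at the onset of coacervation (LCST
behavior). The absorbance at 500 nm along a heating ramp is min-max
normalized and fitted with the logistic sigmoid

    turbidity(T) = 1 / (1 + exp(-k (T - T_cp)))

so the cloud point T_cp is the temperature where the fitted curve crosses
one half, and k (1/K) is the transition steepness. Heating branches are
used for T_cp; cooling branches show nucleation hysteresis and are kept
separate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class TurbidityCurve:
    """A turbidity-vs-temperature trace along one thermal branch."""

    T: np.ndarray            # temperature, K
    A500: np.ndarray         # absorbance at 500 nm (dimensionless)
    branch: str = "heating"  # "heating" or "cooling"
    normalized: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        A = np.asarray(self.A500, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "A500", A)
        if T.shape != A.shape or T.ndim != 1:
            raise ValueError("T and A500 must be 1-D arrays of equal length")
        dT = np.diff(T)
        if len(T) >= 2 and not (np.all(dT > 0) or np.all(dT < 0)):
            raise ValueError("temperature must be strictly monotone within a branch")
        if self.branch not in ("heating", "cooling"):
            raise ValueError("branch must be 'heating' or 'cooling'")


def sigmoid(T: np.ndarray, k: float, T_cp: float) -> np.ndarray:
    """Normalized turbidity model, exactly 0.5 at T = T_cp."""
    # clip the exponent to keep curve_fit finite for wild trial parameters
    x = np.clip(-k * (np.asarray(T, dtype=float) - T_cp), -700, 700)
    return 1.0 / (1.0 + np.exp(x))


def normalize(curve: TurbidityCurve) -> TurbidityCurve:
    """Min-max normalize the absorbance to [0, 1]; temperatures untouched.

    Per-curve normalization removes slow amplitude decay between thermal
    cycles (e.g. from RNA degradation) by construction.
    """
    if len(curve.T) < 4:
        raise ValueError("need at least 4 points to normalize a transition")
    a = curve.A500
    lo, hi = float(np.min(a)), float(np.max(a))
    if hi - lo <= 0:
        raise ValueError("constant signal: no transition to normalize")
    return replace(curve, A500=(a - lo) / (hi - lo), normalized=True)


@dataclass(frozen=True)
class CloudPointFit:
    """Sigmoid fit result: the fitted curve equals 0.5 at T_cp exactly."""

    T_cp: float          # cloud-point temperature, K
    k: float             # steepness, 1/K
    residual: float      # sum of squared residuals
    cov: np.ndarray      # 2x2 covariance of (k, T_cp)
    branch: str = "heating"
    inverted: bool = False   # k <= 0 at optimum (transition runs backwards)
    label: str = ""

    @property
    def se(self) -> tuple[float, float]:
        """Standard errors of (k, T_cp)."""
        d = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        return float(d[0]), float(d[1])

    def predict(self, T: np.ndarray) -> np.ndarray:
        return sigmoid(T, self.k, self.T_cp)

    def summary(self) -> str:
        se_k, se_t = self.se
        flag = "  [inverted transition]" if self.inverted else ""
        return (
            f"Cloud-point sigmoid fit ({self.branch} branch){flag}\n"
            f"  T_cp = {self.T_cp:.3f} +/- {se_t:.3f} K\n"
            f"  k    = {self.k:.3f} +/- {se_k:.3f} 1/K\n"
            f"  SSR  = {self.residual:.3e}"
        )


def initial_guess(T: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Robust starting point: T_cp at the first 0.5-crossing by linear
    interpolation, k = 4 / (T90 - T10) for a monotone sigmoid."""
    T = np.asarray(T, float)
    y = np.asarray(y, float)
    order = np.argsort(T)
    Ts, ys = T[order], y[order]

    def crossing(level: float) -> float:
        above = ys >= level
        idx = np.nonzero(above[1:] != above[:-1])[0]
        if len(idx) == 0:
            return float(Ts[len(Ts) // 2])
        i = idx[0]
        y0, y1 = ys[i], ys[i + 1]
        if y1 == y0:
            return float(Ts[i])
        return float(Ts[i] + (level - y0) * (Ts[i + 1] - Ts[i]) / (y1 - y0))

    t50 = crossing(0.5)
    t10, t90 = crossing(0.1), crossing(0.9)
    width = abs(t90 - t10)
    k0 = 4.0 / width if width > 0 else 4.0 / max(np.ptp(Ts), 1e-6)
    return k0, t50


def fit_cloud_point(curve: TurbidityCurve) -> CloudPointFit:
    """Least-squares (k, T_cp) fit of a normalized turbidity curve.

    Unweighted least squares; the curve is normalized first if needed.
    A step-like transition returns a large finite k and is flagged only if
    the optimum has k <= 0 (inverted transition).
    """
    if not curve.normalized:
        curve = normalize(curve)
    k0, t0 = initial_guess(curve.T, curve.A500)
    try:
        popt, pcov = curve_fit(
            sigmoid, curve.T, curve.A500, p0=(k0, t0),
            maxfev=20000, xtol=1e-12, ftol=1e-12,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"sigmoid fit did not converge (initial guess k={k0:.3g}, "
            f"T_cp={t0:.6g} K): {err}"
        ) from err
    k, t_cp = float(popt[0]), float(popt[1])
    resid = float(np.sum((sigmoid(curve.T, k, t_cp) - curve.A500) ** 2))
    inverted = k <= 0
    if inverted:
        # report the equivalent forward parameterization but keep the flag
        k = abs(k)
    return CloudPointFit(T_cp=t_cp, k=k, residual=resid, cov=np.asarray(pcov),
                         branch=curve.branch, inverted=inverted, label=curve.label)


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_curves(path: str | Path) -> list[TurbidityCurve]:
    """Read (T, A500[, branch][, label]) curves from a delimited file.

    Columns: ``T`` (K), ``A500``; optional ``branch`` and ``label``
    distinguish several curves per file.
    """
    df = pd.read_csv(path)
    required = {"T", "A500"}
    if not required <= set(df.columns):
        raise ValueError(f"need columns {sorted(required)} in {path}")
    if "branch" not in df.columns:
        df["branch"] = "heating"
    if "label" not in df.columns:
        df["label"] = ""
    curves = []
    for (label, branch), g in df.groupby(["label", "branch"], sort=False):
        curves.append(TurbidityCurve(
            T=g["T"].to_numpy(), A500=g["A500"].to_numpy(),
            branch=str(branch), label=str(label)))
    return curves


def write_curves(curves: list[TurbidityCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"label": c.label, "branch": c.branch,
                      "T": c.T, "A500": c.A500})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fits_table(fits: list[CloudPointFit]) -> pd.DataFrame:
    """Tabulate fit results (label, branch, T_cp, k, standard errors)."""
    rows = []
    for f in fits:
        se_k, se_t = f.se
        rows.append({"label": f.label, "branch": f.branch,
                     "T_cp_K": f.T_cp, "T_cp_se": se_t,
                     "k_perK": f.k, "k_se": se_k,
                     "ssr": f.residual, "inverted": f.inverted})
    return pd.DataFrame(rows)
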