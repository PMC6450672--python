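"""Synthetic inputs for every analysis stage.

The package analyses three kinds of input: turbidity-temperature traces,
cloud-point grids over ([tau], [NaCl]), and charged sequences. This module
generates all three from known ground truth so that each stage can be
exercised and its parameter recovery quantified without any measured data:
noisy logistic turbidity sigmoids (with optional per-cycle amplitude decay
mimicking RNA degradation), cloud-point tables produced by the FH-VO
forward model from a chosen chi(T) law, and random charge sequences with
controlled net charge and charge clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloudpoint import TurbidityCurve
from .fhvo import ChiLaw, MixtureParams, DEFAULT_PARAMS, cloud_point_temperature
from .sequences import ChargedSequence

#: experimental ranges the default grids stay inside
TAU_RANGE_UM = (2.0, 240.0)
NACL_RANGE_MM = (30.0, 120.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth plus sampling plan for one synthetic dataset.

    ``truth`` is either a :class:`ChiLaw` (for cloud-point grids) or a list
    of (T_cp, k) pairs (for turbidity curves). ``noise_sd`` is the Gaussian
    standard deviation applied to normalized turbidity (dimensionless) or
    to T_cp (K) depending on the generator. ``decay`` multiplies the raw
    turbidity amplitude once per successive cycle.
    """

    truth: object
    tau_uM: tuple[float, ...] = (10.0, 25.0, 50.0, 100.0)
    nacl_mM: tuple[float, ...] = (30.0, 60.0, 120.0)
    noise_sd: float = 0.0
    decay: float = 1.0
    seed: int = 0
    T_grid: tuple[float, ...] = tuple(np.arange(284.0, 312.25, 0.25))

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must lie in (0, 1]")
        for t in self.tau_uM:
            if not TAU_RANGE_UM[0] <= t <= TAU_RANGE_UM[1]:
                raise ValueError(f"[tau] = {t} uM outside supported range")
        for s in self.nacl_mM:
            if not NACL_RANGE_MM[0] <= s <= NACL_RANGE_MM[1]:
                raise ValueError(f"[NaCl] = {s} mM outside supported range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_turbidity(spec: SyntheticSpec) -> list[TurbidityCurve]:
    """Heating-branch turbidity sigmoids with noise and cycle decay.

    ``spec.truth`` must be a sequence of (T_cp, k) pairs, one per thermal
    cycle. The raw amplitude of cycle i is ``decay ** i``, emulating the
    slow signal loss across repeated ramps; min-max normalization removes
    it again, so the fitted T_cp is decay-invariant by construction.
    """
    rng = spec.rng()
    T = np.asarray(spec.T_grid, dtype=float)
    curves = []
    for i, (t_cp, k) in enumerate(spec.truth):
        amp = spec.decay**i
        y = amp / (1.0 + np.exp(np.clip(-k * (T - t_cp), -700, 700)))
        y = y + spec.noise_sd * amp * rng.standard_normal(T.shape)
        curves.append(TurbidityCurve(T=T, A500=y, branch="heating",
                                     label=f"cycle{i + 1}"))
    return curves


def gen_cloudpoint_grid(spec: SyntheticSpec,
                        params: MixtureParams = DEFAULT_PARAMS,
                        T_range: tuple[float, float] = (274.0, 372.0)) -> pd.DataFrame:
    """Cloud-point table from the FH-VO forward model plus T_cp noise.

    For every ([tau], [NaCl]) grid point the dilute-branch cloud point is
    computed from ``spec.truth`` (an LCST-type :class:`ChiLaw`) and
    perturbed with Gaussian noise of ``spec.noise_sd`` kelvin. Points that
    are single-phase at every temperature in ``T_range`` are kept in the
    table with ``T_cp = NaN`` — marked missing, never fabricated.
    """
    law = spec.truth
    if not isinstance(law, ChiLaw):
        raise TypeError("gen_cloudpoint_grid needs a ChiLaw ground truth")
    if not law.lcst_like:
        raise ValueError("truth must be LCST-like (B < 0) for cloud points")
    rng = spec.rng()
    rows = []
    for tau in spec.tau_uM:
        for salt in spec.nacl_mM:
            t_cp = cloud_point_temperature(tau, salt, law, params=params,
                                           T_range=T_range)
            if t_cp is not None and spec.noise_sd > 0:
                t_cp = t_cp + spec.noise_sd * rng.standard_normal()
            rows.append({"tau_uM": tau, "nacl_mM": salt,
                         "T_cp": np.nan if t_cp is None else t_cp})
    return pd.DataFrame(rows)


def gen_sequences(n_chains: int, length: int, net_charge: int,
                  blockiness: float = 0.0, seed: int = 0) -> list[ChargedSequence]:
    """Random charged chains with exact net charge and tunable clustering.

    The composition is fixed by ``net_charge``: with p positive (K) and m
    negative (E) monomers, p - m = net_charge and p + m is the largest
    feasible count of charged monomers with the required sign balance
    (every chain here is strongly charged; dilute-charge chains can be made
    by concatenating with neutral stretches). ``blockiness`` in [0, 1]
    interpolates between a random shuffle (0) and fully segregated charge
    blocks (1) at identical composition, moving only the charge
    autocorrelation.
    """
    if abs(net_charge) > length:
        raise ValueError("|net_charge| cannot exceed the chain length")
    if not 0.0 <= blockiness <= 1.0:
        raise ValueError("blockiness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_charged = length if (length - abs(net_charge)) % 2 == 0 else length - 1
    p = (n_charged + net_charge) // 2
    m = n_charged - p
    if p < 0 or m < 0:
        raise ValueError("infeasible net charge for this length")
    letters = {1: "K", -1: "E", 0: "G"}
    chains = []
    for i in range(n_chains):
        blocks = [1] * p + [-1] * m + [0] * (length - p - m)
        z = np.array(blocks)  # fully blocky arrangement
        shuffled = z.copy()
        rng.shuffle(shuffled)
        # interpolate: swap a (1 - blockiness) fraction of positions toward
        # the shuffled arrangement while keeping the composition exact
        n_swap = int(round((1.0 - blockiness) * length))
        order = rng.permutation(length)[:n_swap]
        z[np.sort(order)] = shuffled[np.sort(order)]
        # the splice can change composition; repair by resampling excess
        z = _repair_composition(z, p, m, rng)
        seq = "".join(letters[int(v)] for v in z)
        chains.append(ChargedSequence(residues=seq, z=tuple(int(v) for v in z),
                                      name=f"synth{i}"))
    return chains


def _repair_composition(z: np.ndarray, p: int, m: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Force exact counts of +1/-1/0 monomers by minimal random swaps."""
    z = z.copy()
    target = {1: p, -1: m, 0: len(z) - p - m}
    for value in (1, -1, 0):
        while int(np.sum(z == value)) > target[value]:
            # find a value in excess and one in deficit and convert
            deficit = [v for v in (1, -1, 0) if int(np.sum(z == v)) < target[v]]
            idx = rng.choice(np.nonzero(z == value)[0])
            z[idx] = deficit[0]
    return z


def charge_autocorrelation(seq: ChargedSequence, lag: int = 1) -> float:
    """Normalized charge autocorrelation at the given lag (clustering gauge)."""
    z = np.asarray(seq.z, dtype=float)
    z = z - z.mean()
    denom = float(np.sum(z * z))
    if denom == 0:
        return 0.0
    return float(np.sum(z[:-lag] * z[lag:]) / denom)
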