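"""Charge models for protein and RNA chains.

Both analysis tracks (the FH-VO lattice model and the field-theoretic
simulation) share a single, deliberately minimal charge assignment: at
neutral pH, aspartate and glutamate carry -1, lysine and arginine +1, and
every other residue -- including histidine and the termini -- is neutral.
PolyU RNA is a fully charged polyanion, one negative charge per nucleotide.

The integer D/E/K/R count is what the coarse-grained models consume. A
Henderson-Hasselbalch estimate (fractional histidine and terminal charges)
is also provided, for documentation and comparison with the commonly quoted
per-molecule net charges, but it is never fed into the models.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: integer charge per residue at pH 7 (all others neutral)
RESIDUE_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

#: side-chain / terminal pKa values for the optional fractional estimate
_PKA_SIDECHAIN = {
    "D": (3.65, -1), "E": (4.25, -1), "C": (8.3, -1), "Y": (10.07, -1),
    "K": (10.53, +1), "R": (12.48, +1), "H": (6.0, +1),
}
_PKA_NTERM = 9.0
_PKA_CTERM = 2.0

#: molar mass of a condensed uridine monophosphate monomer, Da
URIDINE_MONOMER_MASS = 306.0


@dataclass(frozen=True)
class ChargedSequence:
    """A chain with per-monomer integer charges.

    Attributes
    ----------
    residues : str
        Amino-acid letters, or ``'U' * N`` for polyU RNA.
    z : tuple of int
        Per-monomer charge in elementary charges; ``len(z) == N``.
    name : str
        Free-form label.
    """

    residues: str
    z: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.z) != len(self.residues):
            raise ValueError("charge list length must equal chain length")

    @property
    def N(self) -> int:
        """Chain length in monomers."""
        return len(self.residues)

    @property
    def q_net(self) -> int:
        """Net charge, elementary charges."""
        return int(sum(self.z))

    @property
    def sigma(self) -> float:
        """Average absolute net charge per monomer, |q_net| / N."""
        return abs(self.q_net) / self.N

    def __len__(self) -> int:
        return self.N


@dataclass(frozen=True)
class SpeciesSpec:
    """A species of the five-component lattice mixture.

    ``role`` is one of ``polycation``, ``polyanion``, ``cation``, ``anion``,
    ``solvent``. Ions and solvent have degree of polymerization N = 1;
    solvent is neutral, monovalent ions carry one charge per monomer.
    """

    name: str
    role: str
    N: int
    sigma: float

    _ROLES = ("polycation", "polyanion", "cation", "anion", "solvent")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.N < 1:
            raise ValueError("degree of polymerization must be >= 1")
        if self.role in ("cation", "anion", "solvent") and self.N != 1:
            raise ValueError("ions and solvent must have N = 1")
        if self.role == "solvent" and self.sigma != 0:
            raise ValueError("solvent must be neutral")
        if self.role in ("cation", "anion") and self.sigma != 1:
            raise ValueError("monovalent ions must have sigma = 1")


def assign_charges(sequence: str, pH: float = 7.0, name: str = "") -> ChargedSequence:
    """Assign integer charges to an amino-acid sequence.

    D, E -> -1; K, R -> +1; all other residues (including H, C, S) -> 0.
    The ``pH`` argument is accepted for interface symmetry; the integer
    model is only meaningful near neutral pH and the assignment does not
    vary with it.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a letter outside the
        20-residue alphabet (the offending position is reported).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    for i, letter in enumerate(seq):
        if letter not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {letter!r} at position {i + 1}")
    z = tuple(RESIDUE_CHARGE.get(letter, 0) for letter in seq)
    return ChargedSequence(residues=seq, z=z, name=name)


def make_polyU(N: int, name: str = "polyU") -> ChargedSequence:
    """A fully charged polyU RNA chain: z = -1 at every position."""
    if N < 1:
        raise ValueError("polyU length must be >= 1")
    return ChargedSequence(residues="U" * N, z=(-1,) * N, name=name)


def polyU_length_from_mass(mass_da: float, monomer_mass: float = URIDINE_MONOMER_MASS) -> int:
    """Monomer count of a polyU chain of given molar mass, floored to int."""
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    return int(math.floor(mass_da / monomer_mass))


def phosphorylate(seq: ChargedSequence, sites: Iterable[int]) -> ChargedSequence:
    """Phosphorylate serine residues: charge at each site set to -2.

    ``sites`` are 0-based indices into the chain. Each site must currently
    be a serine (charge 0), so the net charge drops by 2 per site.
    """
    z = list(seq.z)
    residues = list(seq.residues)
    for s in sites:
        if not 0 <= s < seq.N:
            raise ValueError(f"site {s} out of range for chain of length {seq.N}")
        if seq.residues[s] != "S":
            raise ValueError(f"site {s} is {seq.residues[s]!r}, not serine")
        z[s] = -2
    return ChargedSequence(residues="".join(residues), z=tuple(z),
                           name=seq.name + ("+P" if list(sites) else ""))


def charge_matched_rna_mass(tau_conc_uM: float, q_tau: float,
                            monomer_mass: float = URIDINE_MONOMER_MASS) -> float:
    """RNA mass concentration (ug/mL) that charge-matches a tau solution.

    At a 1:1 charge ratio the nucleotide molar concentration equals
    ``q_tau * [tau]``, so the mass concentration is
    ``[tau] (uM) * q_tau * monomer_mass * 1e-3`` in ug/mL.
    """
    if tau_conc_uM < 0:
        raise ValueError("concentration must be >= 0")
    if q_tau <= 0:
        raise ValueError("tau net charge must be positive")
    return tau_conc_uM * q_tau * monomer_mass * 1e-3


def fractional_net_charge(sequence: str, pH: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge estimate (documentation only).

    Includes fractional side-chain charges (D, E, C, Y, K, R, H) and the
    terminal amine/carboxylate. This mirrors the web calculators commonly
    used to quote per-molecule charges; the coarse-grained models use the
    integer D/E/K/R count instead.
    """
    q = 1.0 / (1.0 + 10 ** (pH - _PKA_NTERM))        # N-terminus
    q -= 1.0 / (1.0 + 10 ** (_PKA_CTERM - pH))       # C-terminus
    for letter in sequence.upper():
        if letter in _PKA_SIDECHAIN:
            pka, sign = _PKA_SIDECHAIN[letter]
            if sign > 0:
                q += 1.0 / (1.0 + 10 ** (pH - pka))
            else:
                q -= 1.0 / (1.0 + 10 ** (pka - pH))
    return q


def read_fasta(path: str | Path) -> list[ChargedSequence]:
    """Read protein sequences from FASTA and assign integer charges."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [assign_charges(str(r.seq), name=r.id) for r in records]


def write_charge_table(seq: ChargedSequence, path: str | Path) -> None:
    """Write a plain-text charge table: position, residue, z."""
    with open(path, "w") as fh:
        fh.write("position\tresidue\tz\n")
        for i, (r, z) in enumerate(zip(seq.residues, seq.z), start=1):
            fh.write(f"{i}\t{r}\t{z}\n")


def load_tau(construct: str = "tau187") -> ChargedSequence:
    """Load a bundled tau construct (``tau187``, ``tau187his`` or ``tau114``).

    tau187 is the N-terminally truncated 4R tau (2N4R residues 255-441)
    with the C291S mutation; tau187his prepends the 20-residue expression
    tag; tau114 is residues 255-368 with the same mutation.
    """
    ref = importlib.resources.files("coacervate") / "data" / "tau_constructs.fasta"
    with importlib.resources.as_file(ref) as path:
        seqs = {s.name: s for s in read_fasta(path)}
    if construct not in seqs:
        raise ValueError(f"unknown construct {construct!r}; have {sorted(seqs)}")
    return seqs[construct]
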