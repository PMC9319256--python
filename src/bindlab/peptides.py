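"""Peptide sequence arithmetic.

Average peptide masses (with terminal-cap adjustments), the empirical
random-coil relation between molecular weight and hydrodynamic radius,
oligomer-order inference from apparent masses, and the sliding-window
fragmentation used to dock long disordered peptides piecewise.

Residue numbering is 1-based and anchored to the parent protein: a
:class:`PeptideSequence` carries ``start_number`` so that residue ``i``
(0-based offset) is parent residue ``start_number + i``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "CAP_DELTAS",
    "PeptideSequence",
    "Fragment",
    "HydroParams",
    "average_mass",
    "make_fragments",
    "random_coil_rh",
    "mass_from_rh",
    "oligomer_order",
]

# Average (isotope-abundance weighted) residue masses in Da, i.e. the mass each
# amino acid contributes inside a chain (free amino acid minus water), from the
# standard atomic weights.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0513,
    "A": 71.0779,
    "S": 87.0773,
    "P": 97.1152,
    "V": 99.1310,
    "T": 101.1039,
    "C": 103.1429,
    "L": 113.1576,
    "I": 113.1576,
    "N": 114.1026,
    "D": 115.0874,
    "Q": 128.1292,
    "K": 128.1723,
    "E": 129.1140,
    "M": 131.1960,
    "H": 137.1393,
    "F": 147.1738,
    "R": 156.1857,
    "Y": 163.1732,
    "W": 186.2099,
}

WATER_MASS = 18.0153

NTermCap = Literal["free", "acetyl", "methyl"]
CTermCap = Literal["free", "amide", "methyl"]

# Mass deltas relative to free termini.  Acetylation swaps an N-terminal H for
# CH3CO (+42.037); C-terminal amidation swaps OH for NH2 (−0.984); the methyl
# caps used in fragment docking add a CH2 relative to the free terminus
# (H -> CH3) on either end.  Exposed as a mutable map so other cap chemistries
# can be configured.
CAP_DELTAS: dict[tuple[str, str], float] = {
    ("n", "free"): 0.0,
    ("n", "acetyl"): 42.0367,
    ("n", "methyl"): 14.0266,
    ("c", "free"): 0.0,
    ("c", "amide"): -0.9847,
    ("c", "methyl"): 14.0266,
}

_VALID_N = ("free", "acetyl", "methyl")
_VALID_C = ("free", "amide", "methyl")


def _validate_residues(residues: str) -> None:
    if not residues:
        raise ValueError("sequence must be non-empty")
    for i, aa in enumerate(residues):
        if aa not in AVERAGE_RESIDUE_MASS:
            raise ValueError(
                f"unknown residue code {aa!r} at position {i} (0-based)"
            )


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide with parent-protein numbering and terminal caps."""

    residues: str
    start_number: int = 1
    n_term_cap: NTermCap = "free"
    c_term_cap: CTermCap = "free"

    def __post_init__(self) -> None:
        _validate_residues(self.residues)
        if self.start_number < 1:
            raise ValueError("start_number must be >= 1")
        if self.n_term_cap not in _VALID_N:
            raise ValueError(f"invalid N-terminal cap {self.n_term_cap!r}")
        if self.c_term_cap not in _VALID_C:
            raise ValueError(f"invalid C-terminal cap {self.c_term_cap!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.residues) - 1

    def residue_numbers(self) -> list[int]:
        return list(range(self.start_number, self.end_number + 1))


@dataclass(frozen=True)
class Fragment(PeptideSequence):
    """A contiguous window of a parent peptide (inherits numbering)."""


@dataclass(frozen=True)
class HydroParams:
    """Random-coil scaling R_h = coefficient * MW^exponent (R_h in nm, MW in Da)."""

    coefficient: float = 0.027  # nm * Da^(-1/2)
    exponent: float = 0.5

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")


def average_mass(seq: PeptideSequence) -> float:
    """Average molecular mass of the peptide in Da, caps included."""
    total = sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq.residues) + WATER_MASS
    total += CAP_DELTAS[("n", seq.n_term_cap)]
    total += CAP_DELTAS[("c", seq.c_term_cap)]
    return total


def make_fragments(
    seq: PeptideSequence, window: int = 7, step: int = 2
) -> list[Fragment]:
    """Sliding-window fragments of ``seq`` for piecewise docking.

    Fragment ``k`` covers offsets ``[k*step, k*step + window)``.  All fragments
    receive methyl caps at both termini except the last one, whose C-terminus
    keeps the parent's cap (for an amidated peptide, the terminal -NH2 is
    maintained).  If ``len(seq) - window`` is not a multiple of ``step`` the
    final exactly-fitting window ends short of the parent C-terminus and a
    warning is issued.
    """
    L = len(seq)
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    n_frag = (L - window) // step + 1
    if (L - window) % step != 0:
        warnings.warn(
            "sequence does not tile exactly: last fragment ends at offset "
            f"{(n_frag - 1) * step + window - 1}, short of the C-terminus",
            stacklevel=2,
        )
    fragments: list[Fragment] = []
    for k in range(n_frag):
        off = k * step
        is_last = k == n_frag - 1
        covers_cterm = is_last and off + window == L
        fragments.append(
            Fragment(
                residues=seq.residues[off : off + window],
                start_number=seq.start_number + off,
                n_term_cap="methyl",
                c_term_cap=seq.c_term_cap if covers_cterm else "methyl",
            )
        )
    return fragments


def random_coil_rh(mass: float, params: HydroParams = HydroParams()) -> float:
    """Expected random-coil hydrodynamic radius in Å for a mass in Da."""
    if mass < 0:
        raise ValueError("mass must be >= 0")
    return 10.0 * params.coefficient * mass**params.exponent


def mass_from_rh(rh: float, params: HydroParams = HydroParams()) -> float:
    """Invert the random-coil relation: mass in Da from R_h in Å."""
    if rh < 0:
        raise ValueError("hydrodynamic radius must be >= 0")
    return (rh / (10.0 * params.coefficient)) ** (1.0 / params.exponent)


def oligomer_order(estimated_mass: float, monomer_mass: float) -> tuple[float, int]:
    """Mass ratio and nearest oligomer order (ties round half away from zero)."""
    if estimated_mass <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be > 0")
    ratio = estimated_mass / monomer_mass
    order = int(math.floor(ratio + 0.5))
    return ratio, order


# Study sequences (PADI4 numbering).  NLS1 is the synthesized 27-mer; the NLS2
# docking analysis covers the extended 490-526 region while the synthesized
# peptide spans 498-526.
NLS1_PADI4 = PeptideSequence(
    "AKKKSTGSSTWPLDPGVEVTLTMKVAS", start_number=58,
    n_term_cap="acetyl", c_term_cap="amide",
)
NLS2_PADI4 = PeptideSequence(
    "YKLFQEQQNEGHGEALLFEGIKKKKQQKI", start_number=498,
    n_term_cap="acetyl", c_term_cap="amide",
)
NLS2_REGION_PADI4 = PeptideSequence(
    "LLASPRSC" + NLS2_PADI4.residues, start_number=490,
    n_term_cap="free", c_term_cap="amide",
)
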