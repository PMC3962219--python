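"""Integer nucleon-count masses for amino-acid residues and peptides.

Every atom contributes its mass number (protons + neutrons): H=1, C=12,
N=14, O=16, S=32.  Selenium is deliberately counted as sulfur so that
selenomethionine (MSE), a routine crystallographic substitution for
methionine, scores identically to MET.  All arithmetic is exact integer
arithmetic; these are unitless mass numbers, not Daltons.

A *residue* mass is the in-chain mass (amino acid minus one water).  A
*peptide* mass adds one water back for the free termini (N-terminal H,
C-terminal OH), so a free cysteine weighs 103 + 18 = 121 = 11**2 — the
only single residue whose peptide mass is a perfect square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "NUCLEON_MASS",
    "RESIDUE_FORMULAS",
    "WATER_MASS",
    "ResidueMassTable",
    "UnknownResidueError",
    "residue_mass",
    "peptide_mass",
]

#: Mass number of each element appearing in canonical residues.
#: Se maps to the sulfur mass number by design (see module docstring).
NUCLEON_MASS: Mapping[str, int] = {"H": 1, "C": 12, "N": 14, "O": 16, "S": 32, "SE": 32}

#: Molecular formula of each residue *as part of a chain* (amino acid minus water).
RESIDUE_FORMULAS: Mapping[str, Mapping[str, int]] = {
    "GLY": {"C": 2, "H": 3, "N": 1, "O": 1},
    "ALA": {"C": 3, "H": 5, "N": 1, "O": 1},
    "SER": {"C": 3, "H": 5, "N": 1, "O": 2},
    "PRO": {"C": 5, "H": 7, "N": 1, "O": 1},
    "VAL": {"C": 5, "H": 9, "N": 1, "O": 1},
    "THR": {"C": 4, "H": 7, "N": 1, "O": 2},
    "CYS": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "LEU": {"C": 6, "H": 11, "N": 1, "O": 1},
    "ILE": {"C": 6, "H": 11, "N": 1, "O": 1},
    "ASN": {"C": 4, "H": 6, "N": 2, "O": 2},
    "ASP": {"C": 4, "H": 5, "N": 1, "O": 3},
    "GLN": {"C": 5, "H": 8, "N": 2, "O": 2},
    "LYS": {"C": 6, "H": 12, "N": 2, "O": 1},
    "GLU": {"C": 5, "H": 7, "N": 1, "O": 3},
    "MET": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "HIS": {"C": 6, "H": 7, "N": 3, "O": 1},
    "PHE": {"C": 9, "H": 9, "N": 1, "O": 1},
    "ARG": {"C": 6, "H": 12, "N": 4, "O": 1},
    "TYR": {"C": 9, "H": 9, "N": 1, "O": 2},
    "TRP": {"C": 11, "H": 10, "N": 2, "O": 1},
    # Selenomethionine: MET formula with Se in place of S; Se counted as S.
    "MSE": {"C": 5, "H": 9, "N": 1, "O": 1, "SE": 1},
}

#: Nucleon mass of one water molecule (the free peptide's terminal H + OH).
WATER_MASS: int = 2 * NUCLEON_MASS["H"] + NUCLEON_MASS["O"]

CANONICAL_RESIDUES: tuple[str, ...] = tuple(c for c in RESIDUE_FORMULAS if c != "MSE")

ONE_TO_THREE: Mapping[str, str] = {
    "G": "GLY", "A": "ALA", "S": "SER", "P": "PRO", "V": "VAL",
    "T": "THR", "C": "CYS", "L": "LEU", "I": "ILE", "N": "ASN",
    "D": "ASP", "Q": "GLN", "K": "LYS", "E": "GLU", "M": "MET",
    "H": "HIS", "F": "PHE", "R": "ARG", "Y": "TYR", "W": "TRP",
}


class UnknownResidueError(KeyError):
    """Raised for a residue code with no defined nucleon mass."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown residue code: {self.code!r}"


def _formula_mass(formula: Mapping[str, int]) -> int:
    return sum(NUCLEON_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue code -> integer nucleon mass, plus the terminal-water constant.

    ``with_water`` controls whether :meth:`peptide` adds one water for the
    free termini.  The default (True) is the convention under which the
    single-cysteine peptide has the square mass 121; it is exposed as a
    switch so the alternative convention can be examined.
    """

    entries: Mapping[str, int] = field(
        default_factory=lambda: {c: _formula_mass(f) for c, f in RESIDUE_FORMULAS.items()}
    )
    water_mass: int = WATER_MASS
    with_water: bool = True

    def residue(self, code: str) -> int:
        """Nucleon mass of one in-chain residue (3-letter code)."""
        try:
            return self.entries[code.upper()]
        except KeyError:
            raise UnknownResidueError(code) from None

    def peptide(self, residues: Iterable[str]) -> int:
        """Nucleon mass of a free peptide given its ordered 3-letter codes."""
        total = 0
        n = 0
        for code in residues:
            total += self.residue(code)
            n += 1
        if n == 0:
            raise ValueError("peptide_mass requires a non-empty residue list")
        return total + (self.water_mass if self.with_water else 0)

    def to_tsv(self) -> str:
        """Two-column TSV snapshot (code, mass), sorted by code."""
        lines = ["code\tmass"]
        lines += [f"{c}\t{m}" for c, m in sorted(self.entries.items())]
        return "\n".join(lines) + "\n"


DEFAULT_TABLE = ResidueMassTable()


def residue_mass(code: str, table: ResidueMassTable = DEFAULT_TABLE) -> int:
    """Integer nucleon mass of a single in-chain residue."""
    return table.residue(code)


def peptide_mass(residues: Iterable[str], table: ResidueMassTable = DEFAULT_TABLE) -> int:
    """Integer nucleon mass of a free peptide (includes terminal water by default)."""
    return table.peptide(residues)
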