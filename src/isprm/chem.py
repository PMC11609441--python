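"""Peptide mass arithmetic and tryptic digestion.

Monoisotopic residue masses come from pyteomics' NIST-derived tables; the
heavy-label deltas are computed from first principles as isotope
substitutions (6x13C + 2x15N for lysine, 6x13C + 4x15N for arginine), which
reproduces the conventional +8.014 / +10.008 Da SILAC-style shifts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

WATER_MASS: float = _pmass.calculate_mass(formula="H2O")
PROTON_MASS: float = _pmass.nist_mass["H+"][0][0]

_C13 = _pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]
_N15 = _pmass.nist_mass["N"][15][0] - _pmass.nist_mass["N"][14][0]

#: Heavy-label mass shifts from stable-isotope substitution.
HEAVY_K_DELTA: float = 6 * _C13 + 2 * _N15  # 8.0142 Da
HEAVY_R_DELTA: float = 6 * _C13 + 4 * _N15  # 10.0083 Da

#: Common fixed/variable modification deltas (Da).
CARBAMIDOMETHYL_DELTA: float = 57.02146
OXIDATION_DELTA: float = 15.99491

#: Kyte-Doolittle hydropathy index, used as a crude reversed-phase
#: retention surrogate and for candidate ranking.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def gravy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy of a sequence (GRAVY score)."""
    _check_sequence(sequence)
    if not sequence:
        raise ValueError("empty sequence")
    return sum(KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus the constants the assay math needs.

    ``residues`` maps single-letter residue codes to residue (not free amino
    acid) monoisotopic masses in Da. Label deltas are the isotope-substitution
    shifts applied to C-terminal K/R of internal-standard peptides.
    """

    residues: dict[str, float] = field(
        default_factory=lambda: dict(_pmass.std_aa_mass)
    )
    water: float = WATER_MASS
    proton: float = PROTON_MASS
    carbamidomethyl: float = CARBAMIDOMETHYL_DELTA
    oxidation: float = OXIDATION_DELTA
    heavy_k: float = HEAVY_K_DELTA
    heavy_r: float = HEAVY_R_DELTA

    def heavy_delta(self, residue: str) -> float:
        if residue == "K":
            return self.heavy_k
        if residue == "R":
            return self.heavy_r
        raise ValueError(f"no heavy label defined for residue {residue!r}")


DEFAULT_MASS_TABLE = ResidueMassTable()


class NonStandardResidueError(ValueError):
    """A sequence contains a letter outside the 20 standard residues."""

    def __init__(self, sequence: str, position: int):
        self.position = position
        self.residue = sequence[position]
        super().__init__(
            f"non-standard residue {self.residue!r} at position {position} "
            f"in {sequence!r}"
        )


def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise NonStandardResidueError(sequence, i)


def digest(protein_sequence: str, *, proline_rule: bool = True) -> list[str]:
    """Tryptic digest: cleave after K or R, optionally suppressed before P.

    Returns the ordered, complete partition of the input (zero missed
    cleavages); concatenating the output reproduces the input exactly.
    """
    _check_sequence(protein_sequence)
    if not protein_sequence:
        return []
    if proline_rule:
        pattern = re.compile(r"(?<=[KR])(?!P)")
    else:
        pattern = re.compile(r"(?<=[KR])")
    peptides = [p for p in pattern.split(protein_sequence) if p]
    return peptides


@dataclass(frozen=True)
class CandidateVerdict:
    sequence: str
    accepted: bool
    reasons: tuple[str, ...]  # empty when accepted


def filter_candidates(
    peptides: list[str],
    *,
    min_length: int = 8,
    max_length: int = 21,
) -> tuple[list[str], list[CandidateVerdict]]:
    """Apply the targeted-assay suitability rules to digest products.

    A peptide is accepted iff its length is within [min_length, max_length],
    it contains no methionine, and it ends in K or R (a fully tryptic
    C-terminus; digest products already carry zero missed cleavages). The
    verdicts enumerate every violated rule, in input order.
    """
    accepted: list[str] = []
    verdicts: list[CandidateVerdict] = []
    for pep in peptides:
        reasons: list[str] = []
        if not (min_length <= len(pep) <= max_length):
            reasons.append(
                f"length {len(pep)} outside [{min_length}, {max_length}]"
            )
        if "M" in pep:
            reasons.append("contains methionine")
        if not pep.endswith(("K", "R")):
            reasons.append("C-terminus not K or R")
        if _internal_cleavage_sites(pep):
            reasons.append("missed cleavage")
        ok = not reasons
        if ok:
            accepted.append(pep)
        verdicts.append(CandidateVerdict(pep, ok, tuple(reasons)))
    return accepted, verdicts


def _internal_cleavage_sites(peptide: str) -> list[int]:
    # K/R before the final residue, not followed by P, would have been cleaved
    sites = []
    for i in range(len(peptide) - 1):
        if peptide[i] in "KR" and peptide[i + 1] != "P":
            sites.append(i)
    return sites


def peptide_mass(
    sequence: str,
    mods: dict[int, float] | None = None,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Monoisotopic mass: sum of residue masses + mod deltas + water.

    ``mods`` maps 0-based residue positions to mass deltas (Da).
    """
    _check_sequence(sequence)
    total = table.water
    for aa in sequence:
        total += table.residues[aa]
    if mods:
        for pos, delta in mods.items():
            if not 0 <= pos < len(sequence):
                raise IndexError(f"modification position {pos} out of range")
            total += delta
    return total


def precursor_mz(mass_da: float, charge: int, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """m/z of a protonated species: (M + z*proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass_da + charge * table.proton) / charge


def fragment_mz(
    sequence: str,
    ion_type: str,
    index: int,
    charge: int,
    mods: dict[int, float] | None = None,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Monoisotopic b/y fragment m/z, including mods on covered residues.

    ``index`` is the fragment ordinal: b_i covers the i N-terminal residues,
    y_i the i C-terminal residues; 1 <= index <= len(sequence) - 1.
    """
    if ion_type not in ("b", "y"):
        raise ValueError(f"ion_type must be 'b' or 'y', got {ion_type!r}")
    if not 1 <= index <= len(sequence) - 1:
        raise IndexError(
            f"fragment index {index} out of range for length {len(sequence)}"
        )
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    _check_sequence(sequence)
    mods = mods or {}
    if ion_type == "b":
        positions = range(index)
    else:
        positions = range(len(sequence) - index, len(sequence))
    residue_sum = sum(table.residues[sequence[i]] for i in positions)
    mod_sum = sum(mods.get(i, 0.0) for i in positions)
    # neutral fragment mass: b = residues; y = residues + water
    neutral = residue_sum + mod_sum
    if ion_type == "y":
        neutral += table.water
    return (neutral + charge * table.proton) / charge
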