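"""Targeted assay panel construction and transition-list I/O.

A panel is a set of heavy/light peptide pairs, each with a fixed list of
fragment-ion transitions. The heavy member of a pair is the spiked
internal standard: same sequence and charge, C-terminal K/R carrying the
isotope label, hence a precursor m/z offset of label_delta / charge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import chem
from .chem import DEFAULT_MASS_TABLE, ResidueMassTable

PANEL_COLUMNS = [
    "protein",
    "sequence",
    "charge",
    "is_heavy",
    "precursor_mz",
    "ion_type",
    "fragment_index",
    "fragment_charge",
    "fragment_mz",
]


@dataclass(frozen=True)
class Transition:
    ion_type: str  # 'b' or 'y'
    fragment_index: int
    fragment_charge: int
    mz: float


@dataclass(frozen=True)
class PeptideSpec:
    """A charged, modified peptide (heavy or light) with its transitions."""

    sequence: str
    charge: int
    is_heavy: bool
    protein_id: str
    mods: tuple[tuple[int, float], ...] = ()  # (position, delta) pairs
    precursor_mz: float = 0.0
    transitions: tuple[Transition, ...] = ()

    @property
    def spec_id(self) -> str:
        label = "H" if self.is_heavy else "L"
        return f"{self.protein_id}|{self.sequence}|{self.charge}|{label}"

    @property
    def pair_id(self) -> str:
        """Identifier shared by the heavy/light partners."""
        return f"{self.protein_id}|{self.sequence}|{self.charge}"

    @property
    def label_delta(self) -> float:
        """Mass shift of the heavy label on the C-terminal residue (Da)."""
        return DEFAULT_MASS_TABLE.heavy_delta(self.sequence[-1])

    def transition_mzs(self) -> list[float]:
        return [t.mz for t in self.transitions]


def make_peptide_spec(
    sequence: str,
    protein_id: str,
    charge: int = 2,
    is_heavy: bool = False,
    n_transitions: int = 5,
    min_fragment_index: int = 3,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> PeptideSpec:
    """Build a PeptideSpec with y-ion transitions.

    Fixed modifications: carbamidomethyl on every Cys; for heavy peptides the
    C-terminal K/R carries the isotope label. Transitions are singly charged
    y-ions, longest first (y_{n-1} down to y_{min_fragment_index}), capped at
    ``n_transitions``; y-ions of a heavy peptide always contain the labeled
    C-terminal residue, so every transition is mass-shifted.
    """
    mods: dict[int, float] = {
        i: table.carbamidomethyl for i, aa in enumerate(sequence) if aa == "C"
    }
    if is_heavy:
        cterm = sequence[-1]
        if cterm not in "KR":
            raise ValueError(
                f"heavy peptide must end in K or R, got {sequence!r}"
            )
        pos = len(sequence) - 1
        mods[pos] = mods.get(pos, 0.0) + table.heavy_delta(cterm)
    mass = chem.peptide_mass(sequence, mods, table)
    mz = chem.precursor_mz(mass, charge, table)
    n = len(sequence)
    indices = list(range(n - 1, min_fragment_index - 1, -1))[:n_transitions]
    if len(indices) < 3:
        raise ValueError(
            f"peptide {sequence!r} yields only {len(indices)} transitions; "
            "at least 3 are required"
        )
    transitions = tuple(
        Transition("y", i, 1, chem.fragment_mz(sequence, "y", i, 1, mods, table))
        for i in indices
    )
    return PeptideSpec(
        sequence=sequence,
        charge=charge,
        is_heavy=is_heavy,
        protein_id=protein_id,
        mods=tuple(sorted(mods.items())),
        precursor_mz=mz,
        transitions=transitions,
    )


@dataclass
class Panel:
    """Heavy/light peptide pairs targeted by the assay."""

    peptides: list[PeptideSpec] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        lights = {p.pair_id for p in self.peptides if not p.is_heavy}
        heavies = {p.pair_id for p in self.peptides if p.is_heavy}
        if lights != heavies:
            missing = lights.symmetric_difference(heavies)
            raise ValueError(f"unpaired heavy/light peptides: {sorted(missing)}")
        for p in self.peptides:
            if len(p.transitions) < 3:
                raise ValueError(
                    f"{p.spec_id}: {len(p.transitions)} transitions; "
                    "every precursor needs at least 3"
                )

    def lights(self) -> list[PeptideSpec]:
        return [p for p in self.peptides if not p.is_heavy]

    def heavies(self) -> list[PeptideSpec]:
        return [p for p in self.peptides if p.is_heavy]

    def pairs(self) -> list[tuple[PeptideSpec, PeptideSpec]]:
        """(heavy, light) pairs in stable panel order."""
        light_by_pair = {p.pair_id: p for p in self.lights()}
        return [(h, light_by_pair[h.pair_id]) for h in self.heavies()]

    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.peptides:
            seen.setdefault(p.protein_id, None)
        return list(seen)

    def by_id(self, spec_id: str) -> PeptideSpec:
        for p in self.peptides:
            if p.spec_id == spec_id:
                return p
        raise KeyError(spec_id)


def candidate_score(sequence: str) -> float:
    """Deterministic surrogate for empirical peptide response (lower = better).

    Prefers lengths near 12 residues and mid-range hydropathy; used in place
    of DDA intensity ranking so that panel construction is reproducible
    without external spectral libraries.
    """
    return abs(len(sequence) - 12) + 2.0 * abs(chem.gravy(sequence))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into {record id: sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def build_panel(
    proteins: dict[str, str],
    peptides_per_protein: int = 2,
    transitions_per_peptide: int = 5,
    charge: int = 2,
    proline_rule: bool = True,
) -> Panel:
    """Design a panel from protein sequences.

    For each protein, digest products are filtered by the assay suitability
    rules, ranked by :func:`candidate_score` (ties broken lexicographically),
    and the top ``peptides_per_protein`` become heavy/light pairs. A peptide
    sequence occurring in more than one protein is not quantotypic and is
    excluded from the panel entirely, with a warning.
    """
    candidates: dict[str, list[str]] = {}
    owners: dict[str, str] = {}
    shared: set[str] = set()
    for protein_id, seq in proteins.items():
        digested = chem.digest(seq, proline_rule=proline_rule)
        accepted, _ = chem.filter_candidates(digested)
        candidates[protein_id] = list(dict.fromkeys(accepted))
        for pep in candidates[protein_id]:
            if pep in owners and owners[pep] != protein_id:
                shared.add(pep)
                warnings.warn(
                    f"peptide {pep} shared by {owners[pep]} and {protein_id}; "
                    "excluded from the panel",
                    stacklevel=2,
                )
            else:
                owners[pep] = protein_id
    peptides: list[PeptideSpec] = []
    for protein_id in proteins:
        unique = [p for p in candidates[protein_id] if p not in shared]
        ranked = sorted(unique, key=lambda p: (candidate_score(p), p))
        if len(ranked) < peptides_per_protein:
            raise ValueError(
                f"protein {protein_id}: only {len(ranked)} accepted candidate "
                f"peptides, need {peptides_per_protein}"
            )
        for pep in ranked[:peptides_per_protein]:
            for is_heavy in (False, True):
                peptides.append(
                    make_peptide_spec(
                        pep,
                        protein_id,
                        charge=charge,
                        is_heavy=is_heavy,
                        n_transitions=transitions_per_peptide,
                    )
                )
    return Panel(peptides)


def write_panel_csv(panel: Panel, path: str | Path) -> None:
    """Write a panel as a long-format transition list (one row/transition)."""
    rows = []
    for p in panel.peptides:
        for t in p.transitions:
            rows.append(
                {
                    "protein": p.protein_id,
                    "sequence": p.sequence,
                    "charge": p.charge,
                    "is_heavy": p.is_heavy,
                    "precursor_mz": p.precursor_mz,
                    "ion_type": t.ion_type,
                    "fragment_index": t.fragment_index,
                    "fragment_charge": t.fragment_charge,
                    "fragment_mz": t.mz,
                }
            )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> Panel:
    """Read a transition-list CSV written by :func:`write_panel_csv`."""
    try:
        # round_trip parser: written m/z values reload bit-identically
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no targets (empty panel file)") from None
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no targets (no transition rows)")
    for col in ("charge", "fragment_index", "fragment_charge"):
        bad = df[~df[col].apply(lambda v: float(v).is_integer())]
        if not bad.empty:
            line = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed {col} at line {line}")
    peptides: list[PeptideSpec] = []
    keys = df[["protein", "sequence", "charge", "is_heavy"]].drop_duplicates()
    for _, key in keys.iterrows():
        grp = df[
            (df["protein"] == key["protein"])
            & (df["sequence"] == key["sequence"])
            & (df["charge"] == key["charge"])
            & (df["is_heavy"] == key["is_heavy"])
        ]
        transitions = tuple(
            Transition(
                row["ion_type"],
                int(row["fragment_index"]),
                int(row["fragment_charge"]),
                float(row["fragment_mz"]),
            )
            for _, row in grp.iterrows()
        )
        if len(transitions) < 3:
            raise ValueError(
                f"{path}: precursor {key['sequence']}/{key['charge']} "
                f"({'heavy' if key['is_heavy'] else 'light'}) has "
                f"{len(transitions)} transitions; at least 3 required"
            )
        seq = str(key["sequence"])
        is_heavy = bool(key["is_heavy"])
        mods: dict[int, float] = {
            i: DEFAULT_MASS_TABLE.carbamidomethyl
            for i, aa in enumerate(seq)
            if aa == "C"
        }
        if is_heavy:
            pos = len(seq) - 1
            mods[pos] = mods.get(pos, 0.0) + DEFAULT_MASS_TABLE.heavy_delta(seq[-1])
        peptides.append(
            PeptideSpec(
                sequence=seq,
                charge=int(key["charge"]),
                is_heavy=is_heavy,
                protein_id=str(key["protein"]),
                mods=tuple(sorted(mods.items())),
                precursor_mz=float(grp["precursor_mz"].iloc[0]),
                transitions=transitions,
            )
        )
    return Panel(peptides)


# ---------------------------------------------------------------------------
# Default nine-protein wound-biomarker panel.
#
# Three peptides are published assay peptides (VNLLSAIK/TNFA, IPVALGLK/IL1B,
# AFQVWSDVTPLR/MMP2); the remaining fifteen are SYNTHETIC stand-in sequences
# that satisfy the selection rules (length 8-21, no Met, tryptic C-terminus,
# no missed cleavages) and are chosen to spread across the hydropathy range.
# ---------------------------------------------------------------------------

#: Ordered lowest- to highest-abundance: the synthetic ground truth assigns
#: its log-spaced concentration grid in this order, mirroring the real
#: situation where the cytokines (TNFA, IL1B) sit orders of magnitude below
#: the structural proteins (collagen, fibronectin).
DEFAULT_PANEL_PEPTIDES: dict[str, tuple[str, str]] = {
    "TNFA": ("VNLLSAIK", "ETPEGAEAK"),
    "IL1B": ("IPVALGLK", "ETNQLVAGYLQGPSK"),
    "MMP9": ("AVIDDAFAR", "SLGPALLLLQK"),
    "MMP2": ("AFQVWSDVTPLR", "GEALQSTDVK"),
    "S100A9": ("NIETIINTFHQYSVK", "DLQNFLSK"),
    "S100A8": ("ALNSIIDVYHK", "LGHPDTLNQGEFK"),
    "ELNE": ("VVLGAHNLSR", "FVNWIDSIIQR"),
    "COL1A1": ("GVQGPPGPAGPR", "DGEAGAQGPPGPAGPAGER"),
    "FN1": ("SYTITGLQPGTDYK", "WLPSSSPVTGYR"),
}


def default_proteins() -> dict[str, str]:
    """Synthetic protein sequences embedding the default panel peptides.

    Each 'protein' is simply the concatenation of its two target peptides,
    so a tryptic digest recovers exactly those peptides. These are synthetic
    stand-ins for testing and simulation, not real protein sequences.
    """
    return {
        pid: p1 + p2 for pid, (p1, p2) in DEFAULT_PANEL_PEPTIDES.items()
    }


def default_panel(transitions_per_peptide: int = 5) -> Panel:
    """The default 9-protein, 18-peptide-pair wound-biomarker panel."""
    return build_panel(
        default_proteins(),
        peptides_per_protein=2,
        transitions_per_peptide=transitions_per_peptide,
    )
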