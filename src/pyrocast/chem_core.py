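"""Molecule parsing, canonicalization, masses and descriptors.

Everything downstream (reaction enumeration, mass-key matching, hazard
lookups, chemical-space analysis) goes through the :class:`Molecule`
wrapper defined here.  RDKit does the heavy lifting; this module pins the
contracts the rest of the pipeline relies on:

* parsing validates valence and raises typed errors naming the offending
  input;
* ``exact_mass`` is the monoisotopic mass (most-abundant isotope of every
  atom, implicit hydrogens included), the quantity the fragment-matching
  rule is built on;
* ``average_mass`` uses standard atomic weights (the scale on which a set
  of volatile flavours averages ~146 Da);
* the six-descriptor vector (MW, nHBDon, nHBAcc, TopoPSA, nRotB, ALogP)
  is fixed in that order for the chemical-space PCA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")  # errors are re-raised as typed exceptions

__all__ = [
    "Molecule",
    "DescriptorVector",
    "SmilesParseError",
    "ValenceError",
    "parse_molecule",
    "exact_mass",
    "average_mass",
    "nominal_mass",
    "descriptor_vector",
    "molecular_formula",
    "inchikey",
    "read_smiles_file",
    "read_smiles_csv",
    "DESCRIPTOR_NAMES",
]

#: fixed column order of the descriptor matrix
DESCRIPTOR_NAMES = ("MW", "nHBDon", "nHBAcc", "TopoPSA", "nRotB", "ALogP")


class SmilesParseError(ValueError):
    """Input text is not a parsable SMILES string."""


class ValenceError(ValueError):
    """Structure violates the organic valence table (e.g. 5-bonded carbon)."""


@dataclass(frozen=True)
class Molecule:
    """A parsed, valence-valid chemical structure.

    ``formula`` maps element symbol -> positive count (implicit hydrogens
    included).  ``canonical_smiles`` round-trips to an identical formula
    and bond multiset.
    """

    rdmol: Chem.Mol = field(repr=False, compare=False)
    canonical_smiles: str
    formula: dict[str, int] = field(compare=False)

    def __hash__(self) -> int:  # canonical SMILES is the identity
        return hash(self.canonical_smiles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.canonical_smiles == other.canonical_smiles

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()


def _formula_counts(rdmol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in rdmol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a valence-valid :class:`Molecule`.

    Implicit hydrogens are completed to fill valence (SMILES convention).
    Raises :class:`SmilesParseError` for syntactically invalid input and
    :class:`ValenceError` when the structure breaks the valence table.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES input")
    smiles = smiles.strip()
    rdmol = Chem.MolFromSmiles(smiles, sanitize=False)
    if rdmol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    try:
        Chem.SanitizeMol(rdmol)
    except (Chem.AtomValenceException, Chem.KekulizeException) as exc:
        raise ValenceError(f"valence violation in {smiles!r}: {exc}") from exc
    except Exception as exc:  # other sanitization failures
        raise SmilesParseError(f"invalid structure {smiles!r}: {exc}") from exc
    return from_rdmol(rdmol)


def from_rdmol(rdmol: Chem.Mol) -> Molecule:
    """Wrap an already-sanitized RDKit mol."""
    canonical = Chem.MolToSmiles(rdmol)
    return Molecule(rdmol=rdmol, canonical_smiles=canonical,
                    formula=_formula_counts(rdmol))


def exact_mass(mol: Molecule) -> float:
    """Monoisotopic mass in Da (sum over most-abundant isotopes, incl. H)."""
    return Descriptors.ExactMolWt(mol.rdmol)


def average_mass(mol: Molecule) -> float:
    """Average molecular weight in Da (standard atomic weights)."""
    return Descriptors.MolWt(mol.rdmol)


def nominal_mass(mol: Molecule) -> int:
    """Integer (unit) mass: monoisotopic mass rounded half-away-from-zero."""
    return round_half_away(exact_mass(mol))


def round_half_away(x: float) -> int:
    """Round to nearest integer with .5 going away from zero.

    Centralized so one constant controls every nominal-mass rounding in
    the pipeline (builtin ``round`` is banker's rounding).
    """
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class DescriptorVector:
    """The six pharmaceutically relevant descriptors, fixed order."""

    mw: float          # Da, average atomic weights
    n_hbd: int         # hydrogen-bond donors
    n_hba: int         # hydrogen-bond acceptors
    tpsa: float        # topological polar surface area, A^2
    n_rotb: int        # rotatable bonds
    alogp: float       # Crippen octanol-water partition coefficient

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mw, self.n_hbd, self.n_hba, self.tpsa, self.n_rotb, self.alogp],
            dtype=float,
        )


def descriptor_vector(mol: Molecule) -> DescriptorVector:
    """Compute the six-descriptor vector (deterministic per structure)."""
    m = mol.rdmol
    vec = DescriptorVector(
        mw=Descriptors.MolWt(m),
        n_hbd=rdMolDescriptors.CalcNumHBD(m),
        n_hba=rdMolDescriptors.CalcNumHBA(m),
        tpsa=Descriptors.TPSA(m),
        n_rotb=Descriptors.NumRotatableBonds(m),
        alogp=Crippen.MolLogP(m),
    )
    if not np.all(np.isfinite(vec.as_array())):
        raise ValueError(f"non-finite descriptor for {mol.canonical_smiles}")
    return vec


def molecular_formula(mol: Molecule) -> str:
    """Hill-order molecular formula string (e.g. ``C5H8O2``)."""
    # strip charge suffixes RDKit appends for ions
    return re.sub(r"[+-]+$", "", rdMolDescriptors.CalcMolFormula(mol.rdmol))


def inchikey(mol: Molecule) -> str:
    """27-character standard InChIKey, the lookup key for hazard tables."""
    key = Chem.MolToInchiKey(mol.rdmol)
    if not key:
        raise ValueError(f"InChIKey generation failed for {mol.canonical_smiles}")
    return key


# ---------------------------------------------------------------------------
# file readers

def read_smiles_file(path) -> list[tuple[str, Molecule]]:
    """Read a .smi file: one SMILES per line, optional tab-separated name.

    Returns (name, Molecule) pairs; unnamed entries get their SMILES as name.
    """
    out: list[tuple[str, Molecule]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            name = parts[1].strip() if len(parts) > 1 and parts[1].strip() else smiles
            try:
                out.append((name, parse_molecule(smiles)))
            except (SmilesParseError, ValenceError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return out


def read_smiles_csv(path) -> list[tuple[str, Molecule]]:
    """Read a CSV with columns ``name,smiles`` (header required)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols or "name" not in cols:
        raise ValueError(f"{path}: expected columns name,smiles; got {list(df.columns)}")
    return [
        (str(row[cols["name"]]), parse_molecule(str(row[cols["smiles"]])))
        for _, row in df.iterrows()
    ]
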