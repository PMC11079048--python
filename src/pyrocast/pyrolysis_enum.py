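"""Candidate unimolecular pyrolysis reactions by bond-change enumeration.

A pyrolysis transformation is modelled as an *edit set*: up to five
simultaneous bond-order changes (hydrogen movements included explicitly,
never silently).  Enumeration works on the explicit-hydrogen, kekulized
molecular graph:

1. candidate bond-breaking positions are ranked weakest-first by mean
   bond enthalpy and capped (default 16 distinct symmetry classes);
2. every combination of 1..max_changes order *decreases* over those
   positions is applied;
3. the freed valences are completed by bond-order *increases* between
   free atoms (a recursive matching search), within the same edit budget;
4. a candidate survives only if every atom ends at exactly the valence it
   had in the reactant — valence-complete, radical-free products — and
   element counts are conserved by construction.

Duplicate product multisets reached through different edit sets collapse
onto the best-scoring edit set.  Scoring is pluggable (``ReactionScorer``
protocol); the shipped baseline scores an edit set by the tabulated mean
bond enthalpies of the bonds it breaks and forms, so weak-bond chemistry
ranks first.  A learned reaction-ranking model can be dropped in through
the same interface.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Protocol

import numpy as np
from rdkit import Chem

from .chem_core import Molecule, from_rdmol

logger = logging.getLogger(__name__)

__all__ = [
    "BondEdit",
    "EditSet",
    "AtomFeatureVector",
    "BondFeatureVector",
    "PyrolysisPrediction",
    "ReactionScorer",
    "ScorerError",
    "AcetateDomainError",
    "wl_atom_features",
    "bond_features",
    "enumerate_candidate_reactions",
    "score_and_rank",
    "baseline_bond_energy_scorer",
    "bond_energy",
    "load_bond_energy_table",
    "acetate_pathway_templates",
    "DEFAULT_TOP_K",
    "DEFAULT_MAX_CHANGES",
    "DEFAULT_MAX_BREAK_SITES",
]

DEFAULT_TOP_K = 25          # predictions kept per flavour
DEFAULT_MAX_CHANGES = 5     # simultaneous bond changes per reaction
DEFAULT_MAX_BREAK_SITES = 16  # distinct bond-breaking positions considered

_ORDER_TO_BONDTYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                      3: Chem.BondType.TRIPLE}
# fallback mean enthalpies (kJ/mol) for element pairs absent from the table
_FALLBACK_BY_ORDER = {1: 300.0, 2: 550.0, 3: 800.0}


class ScorerError(ValueError):
    """A scorer returned a non-finite value for a candidate."""


class AcetateDomainError(ValueError):
    """Input molecule carries no acetate ester group."""


# ---------------------------------------------------------------------------
# feature vectors (graph-kernel style atom/bond attributes)

@dataclass(frozen=True)
class AtomFeatureVector:
    """Raw per-atom attributes of the molecular graph."""

    atomic_number: int
    degree: int          # connected heavy atoms
    total_valence: int   # total bond order including hydrogens
    formal_charge: int
    aromatic: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.atomic_number, self.degree, self.total_valence,
                         self.formal_charge, int(self.aromatic)], dtype=float)


@dataclass(frozen=True)
class BondFeatureVector:
    atom_i: int
    atom_j: int
    bond_order: float    # 1, 2, 3 or 1.5 for aromatic
    in_ring: bool
    conjugated: bool


def wl_atom_features(mol: Molecule) -> tuple[list[AtomFeatureVector], np.ndarray]:
    """Per-atom feature vectors plus one round of neighbor aggregation.

    The aggregated array (n_atoms x 5) is each atom's raw vector summed
    with those of its directly bonded neighbors — the one-iteration
    graph-kernel update that lets an atom's representation carry local
    context.
    """
    raw = [
        AtomFeatureVector(
            atomic_number=a.GetAtomicNum(),
            degree=a.GetDegree(),
            total_valence=a.GetTotalValence(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.rdmol.GetAtoms()
    ]
    mat = np.stack([f.as_array() for f in raw])
    agg = mat.copy()
    for bond in mol.rdmol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        agg[i] += mat[j]
        agg[j] += mat[i]
    return raw, agg


def bond_features(mol: Molecule) -> list[BondFeatureVector]:
    """Per-bond order / ring / conjugation attributes."""
    out = []
    for b in mol.rdmol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        out.append(BondFeatureVector(
            atom_i=i, atom_j=j,
            bond_order=b.GetBondTypeAsDouble(),
            in_ring=b.IsInRing(),
            conjugated=b.GetIsConjugated(),
        ))
    return out


# ---------------------------------------------------------------------------
# edit sets

@dataclass(frozen=True)
class BondEdit:
    """One bond-order change between a pair of atoms (explicit-H indexing)."""

    atom_i: int
    atom_j: int
    old_order: int
    new_order: int
    elem_i: str = ""
    elem_j: str = ""

    def __post_init__(self):
        if not self.atom_i < self.atom_j:
            raise ValueError("BondEdit requires atom_i < atom_j")
        if self.old_order == self.new_order:
            raise ValueError("BondEdit requires old_order != new_order")
        if not (0 <= self.old_order <= 3 and 0 <= self.new_order <= 3):
            raise ValueError("bond orders must be in 0..3")

    @property
    def involves_hydrogen(self) -> bool:
        return "H" in (self.elem_i, self.elem_j)


@dataclass(frozen=True)
class EditSet:
    """1-5 simultaneous bond edits; hydrogen moves are explicit edits."""

    edits: tuple[BondEdit, ...]

    def __post_init__(self):
        if not 1 <= len(self.edits) <= 5:
            raise ValueError("an EditSet holds 1 to 5 edits")
        pairs = [(e.atom_i, e.atom_j) for e in self.edits]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicated atom pair in EditSet")

    @property
    def hydrogen_edits(self) -> tuple[BondEdit, ...]:
        """The implicit-H rebalancing record: edits touching a hydrogen."""
        return tuple(e for e in self.edits if e.involves_hydrogen)

    def summary(self) -> str:
        return ";".join(
            f"{e.elem_i}{e.atom_i}-{e.elem_j}{e.atom_j}:{e.old_order}>{e.new_order}"
            for e in self.edits
        )


@dataclass(frozen=True)
class PyrolysisPrediction:
    rank: int
    score: float
    edit_set: EditSet
    products: tuple[Molecule, ...]


# ---------------------------------------------------------------------------
# bond-energy table

def load_bond_energy_table(path=None) -> dict[str, float]:
    """Load the mean bond enthalpy table (kJ/mol), JSON keyed ``El-El:order``."""
    if path is None:
        text = resources.files("pyrocast.data").joinpath("bond_energies.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


_DEFAULT_TABLE = load_bond_energy_table()
_warned_pairs: set[str] = set()


def bond_energy(elem_a: str, elem_b: str, order: int,
                table: dict[str, float] | None = None) -> float:
    """Tabulated mean bond enthalpy (kJ/mol); 0 for order 0.

    Element pairs absent from the table fall back to an order-level
    default (logged once per pair).
    """
    if order == 0:
        return 0.0
    table = _DEFAULT_TABLE if table is None else table
    key = f"{'-'.join(sorted((elem_a, elem_b)))}:{order}"
    if key in table:
        return table[key]
    if key not in _warned_pairs:
        _warned_pairs.add(key)
        logger.warning("no bond energy for %s; using order-%d default %.0f kJ/mol",
                       key, order, _FALLBACK_BY_ORDER[order])
    return _FALLBACK_BY_ORDER[order]


def baseline_bond_energy_scorer(reactant: Molecule, edits: EditSet | None,
                                products, table: dict[str, float] | None = None) -> float:
    """Deterministic stand-in for a learned reaction ranker.

    Score = -(sum of enthalpies of bonds broken - sum formed)
          = sum over edits of E(new order) - E(old order), in kJ/mol.
    Less endothermic bond reorganizations score higher.  A null edit set
    scores 0.
    """
    if edits is None:
        return 0.0
    return float(sum(
        bond_energy(e.elem_i, e.elem_j, e.new_order, table)
        - bond_energy(e.elem_i, e.elem_j, e.old_order, table)
        for e in edits.edits
    ))


class ReactionScorer(Protocol):
    def __call__(self, reactant: Molecule, edits: EditSet | None,
                 products: tuple[Molecule, ...]) -> float: ...


# ---------------------------------------------------------------------------
# enumeration

def _explicit_graph(mol: Molecule):
    """Kekulized explicit-H copy -> (rdmol, symbols, target valences, bonds)."""
    rdmol = Chem.AddHs(mol.rdmol)
    Chem.Kekulize(rdmol, clearAromaticFlags=True)
    symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
    bonds: dict[tuple[int, int], int] = {}
    for b in rdmol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bonds[(i, j)] = int(b.GetBondTypeAsDouble())
    target = [0] * rdmol.GetNumAtoms()
    for (i, j), order in bonds.items():
        target[i] += order
        target[j] += order
    return rdmol, symbols, target, bonds


def _products_from_bonds(symbols, bonds, free=None) -> tuple[Molecule, ...] | None:
    """Assemble product molecules from an edited bond dict; None if invalid."""
    rw = Chem.RWMol()
    for sym in symbols:
        atom = Chem.Atom(sym)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    if free is not None:
        for idx, f in enumerate(free):
            if f:
                rw.GetAtomWithIdx(idx).SetNumRadicalElectrons(int(f))
    for (i, j), order in bonds.items():
        if order:
            rw.AddBond(i, j, _ORDER_TO_BONDTYPE[order])
    try:
        prod = rw.GetMol()
        Chem.SanitizeMol(prod)
        frags = Chem.GetMolFrags(prod, asMols=True, sanitizeFrags=True)
        return tuple(sorted(
            (from_rdmol(Chem.RemoveHs(f)) for f in frags),
            key=lambda m: m.canonical_smiles,
        ))
    except Exception:  # pragma: no cover - defensive: our states are valence-checked
        return None


def enumerate_candidate_reactions(
    mol: Molecule,
    max_changes: int = DEFAULT_MAX_CHANGES,
    max_break_sites: int = DEFAULT_MAX_BREAK_SITES,
    allow_radicals: bool = False,
    bond_table: dict[str, float] | None = None,
) -> list[tuple[EditSet, tuple[Molecule, ...]]]:
    """Enumerate valence-valid unimolecular transformations of ``mol``.

    Returns deduplicated (EditSet, products) candidates; for each distinct
    product multiset the best edit set under the baseline bond-energy
    score is kept.  An empty list is a valid result (no feasible
    radical-free chemistry within the edit budget).

    ``max_break_sites`` caps the distinct bond symmetry classes considered
    for cleavage, weakest (lowest mean bond enthalpy) first.  With
    ``allow_radicals`` the valence-completeness requirement is relaxed to
    admit mono-/di-radical product sets (off by default).
    """
    if not 1 <= max_changes <= 5:
        raise ValueError("max_changes must be in 1..5")
    if mol.rdmol.GetNumHeavyAtoms() < 2:
        return []
    rdmol, symbols, target, bonds0 = _explicit_graph(mol)

    # cap the number of distinct bond symmetry classes considered for
    # cleavage (weakest mean bond enthalpy first); all member bonds of a
    # selected class stay available so multi-bond edits within one class
    # (e.g. two C-H cleavages for an H2 elimination) remain reachable
    ranks = list(Chem.CanonicalRankAtoms(rdmol, breakTies=False))
    by_class: dict[tuple, list[tuple[int, int, int]]] = {}
    for (i, j), order in sorted(bonds0.items()):
        cls = (min(ranks[i], ranks[j]), max(ranks[i], ranks[j]), order)
        by_class.setdefault(cls, []).append((i, j, order))
    classes = sorted(
        by_class,
        key=lambda c: (bond_energy(symbols[by_class[c][0][0]],
                                   symbols[by_class[c][0][1]],
                                   c[2], bond_table), c),
    )[:max_break_sites]
    break_cands = sorted(b for c in classes for b in by_class[c])

    best: dict[tuple[str, ...], tuple[float, EditSet, tuple[Molecule, ...]]] = {}
    reactant_key = (mol.canonical_smiles,)
    free = [0] * len(symbols)
    product_cache: dict[frozenset, tuple[Molecule, ...] | None] = {}

    def record(edits: list[BondEdit], bonds: dict, radical: bool):
        state_key = frozenset((*ij, order) for ij, order in bonds.items() if order)
        if radical:
            products = _products_from_bonds(symbols, bonds, free=free)
        elif state_key in product_cache:
            products = product_cache[state_key]
        else:
            products = _products_from_bonds(symbols, bonds)
            product_cache[state_key] = products
        if products is None:
            return
        key = tuple(p.canonical_smiles for p in products)
        if key == reactant_key:
            return  # identity / degenerate rearrangement
        edit_set = EditSet(edits=tuple(sorted(
            edits, key=lambda e: (e.atom_i, e.atom_j))))
        score = baseline_bond_energy_scorer(mol, edit_set, products, bond_table)
        prev = best.get(key)
        if prev is None or (score, -len(edit_set.edits)) > (prev[0], -len(prev[1].edits)):
            best[key] = (score, edit_set, products)

    def complete(edits: list[BondEdit], bonds: dict, budget: int,
                 pivot_partner_floor: int):
        free_atoms = [a for a, f in enumerate(free) if f > 0]
        if not free_atoms:
            record(edits, bonds, radical=False)
            return
        if allow_radicals and sum(free) <= 2:
            record(edits, bonds, radical=True)
        if budget == 0 or math.ceil(len(free_atoms) / 2) > budget:
            return
        a = free_atoms[0]
        edited_pairs = {(e.atom_i, e.atom_j) for e in edits}
        for b in free_atoms[1:]:
            if b < pivot_partner_floor:
                continue
            pair = (a, b) if a < b else (b, a)
            if pair in edited_pairs:
                continue
            old = bonds.get(pair, 0)
            max_delta = min(free[a], free[b], 3 - old)
            for delta in range(1, max_delta + 1):
                new = old + delta
                bonds[pair] = new
                free[a] -= delta
                free[b] -= delta
                edits.append(BondEdit(pair[0], pair[1], old, new,
                                      symbols[pair[0]], symbols[pair[1]]))
                next_floor = b + 1 if free[a] > 0 else 0
                complete(edits, bonds, budget - 1, next_floor)
                edits.pop()
                free[a] += delta
                free[b] += delta
                if old:
                    bonds[pair] = old
                else:
                    del bonds[pair]

    for n_breaks in range(1, max_changes + 1):
        for combo in itertools.combinations(break_cands, n_breaks):
            order_choices = [range(order) for (_, _, order) in combo]
            for new_orders in itertools.product(*order_choices):
                bonds = dict(bonds0)
                edits: list[BondEdit] = []
                for (i, j, old), new in zip(combo, new_orders):
                    if new:
                        bonds[(i, j)] = new
                    else:
                        del bonds[(i, j)]
                    free[i] += old - new
                    free[j] += old - new
                    edits.append(BondEdit(i, j, old, new, symbols[i], symbols[j]))
                complete(edits, bonds, max_changes - n_breaks, 0)
                for (i, j, old), new in zip(combo, new_orders):
                    free[i] -= old - new
                    free[j] -= old - new

    out = [(es, prods) for _, es, prods in best.values()]
    out.sort(key=lambda c: tuple(p.canonical_smiles for p in c[1]))
    return out


def score_and_rank(
    reactant: Molecule,
    candidates: list[tuple[EditSet, tuple[Molecule, ...]]],
    scorer: ReactionScorer | None = None,
    top_k: int = DEFAULT_TOP_K,
) -> list[PyrolysisPrediction]:
    """Score candidates and rank the top ``top_k`` (descending score).

    Equal scores tie-break on the lexicographic canonical product SMILES,
    so the output is a permutation-stable total order.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    scorer = scorer or baseline_bond_energy_scorer
    scored = []
    for edit_set, products in candidates:
        s = float(scorer(reactant, edit_set, products))
        if not math.isfinite(s):
            raise ScorerError(
                f"non-finite score {s!r} for candidate "
                f"{[p.canonical_smiles for p in products]}")
        scored.append((s, tuple(p.canonical_smiles for p in products),
                       edit_set, products))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        PyrolysisPrediction(rank=r, score=s, edit_set=es, products=prods)
        for r, (s, _, es, prods) in enumerate(scored[:top_k], start=1)
    ]


# ---------------------------------------------------------------------------
# acetate ester elimination templates

_ACETATE_SMARTS = Chem.MolFromSmarts("[CH3][CX3](=O)[OX2][#6]")


def acetate_pathway_templates(ester: Molecule) -> dict[str, tuple[Molecule, ...] | None]:
    """The three elimination pathways of an acetate ester CH3C(=O)O-R.

    A: acetic acid + alkene (needs an sp3 alkoxy carbon with a beta-H on
       a neighbouring carbon);
    B: ketene + the substituted alcohol R-OH (always available);
    C: C-O cleavage to two carbonyls, acetaldehyde + R'CH=O (needs an H
       on the alkoxy carbon).
    Pathways whose structural precondition fails map to None.
    Raises :class:`AcetateDomainError` when no acetate group is present.
    """
    matches = ester.rdmol.GetSubstructMatches(_ACETATE_SMARTS)
    if not matches:
        raise AcetateDomainError(
            f"no acetate ester group in {ester.canonical_smiles}")
    c_me, c_carbonyl, o_carbonyl, o_ester, c_alkoxy = matches[0]
    molh = Chem.AddHs(ester.rdmol)

    def h_neighbor(idx: int) -> int | None:
        for nb in molh.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetAtomicNum() == 1:
                return nb.GetIdx()
        return None

    def fragments(edit_fn) -> tuple[Molecule, ...]:
        rw = Chem.RWMol(molh)
        edit_fn(rw)
        prod = rw.GetMol()
        Chem.SanitizeMol(prod)
        frags = Chem.GetMolFrags(prod, asMols=True, sanitizeFrags=True)
        return tuple(sorted((from_rdmol(Chem.RemoveHs(f)) for f in frags),
                            key=lambda m: m.canonical_smiles))

    out: dict[str, tuple[Molecule, ...] | None] = {"A": None, "B": None, "C": None}

    alkoxy_atom = ester.rdmol.GetAtomWithIdx(c_alkoxy)
    if not alkoxy_atom.GetIsAromatic() and alkoxy_atom.GetHybridization() == Chem.HybridizationType.SP3:
        beta = None
        for nb in molh.GetAtomWithIdx(c_alkoxy).GetNeighbors():
            if nb.GetAtomicNum() == 6 and nb.GetIdx() != c_carbonyl \
                    and h_neighbor(nb.GetIdx()) is not None:
                beta = nb.GetIdx()
                break
        if beta is not None:
            h_beta = h_neighbor(beta)

            def edit_a(rw):
                rw.RemoveBond(o_ester, c_alkoxy)
                rw.RemoveBond(beta, h_beta)
                rw.AddBond(o_ester, h_beta, Chem.BondType.SINGLE)
                rw.GetBondBetweenAtoms(c_alkoxy, beta).SetBondType(Chem.BondType.DOUBLE)

            out["A"] = fragments(edit_a)

    h_me = h_neighbor(c_me)

    def edit_b(rw):
        rw.RemoveBond(c_carbonyl, o_ester)
        rw.RemoveBond(c_me, h_me)
        rw.AddBond(o_ester, h_me, Chem.BondType.SINGLE)
        rw.GetBondBetweenAtoms(c_me, c_carbonyl).SetBondType(Chem.BondType.DOUBLE)

    out["B"] = fragments(edit_b)

    h_alkoxy = h_neighbor(c_alkoxy)
    if h_alkoxy is not None:

        def edit_c(rw):
            rw.RemoveBond(c_carbonyl, o_ester)
            rw.RemoveBond(c_alkoxy, h_alkoxy)
            rw.AddBond(c_carbonyl, h_alkoxy, Chem.BondType.SINGLE)
            rw.GetBondBetweenAtoms(o_ester, c_alkoxy).SetBondType(Chem.BondType.DOUBLE)

        out["C"] = fragments(edit_c)

    return out
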