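import itertools
import random
from collections import Counter

import pytest
from rdkit import Chem

from pyrocast.chem_core import parse_molecule
from pyrocast.pyrolysis_enum import (
    AcetateDomainError,
    BondEdit,
    EditSet,
    ScorerError,
    acetate_pathway_templates,
    baseline_bond_energy_scorer,
    bond_energy,
    bond_features,
    enumerate_candidate_reactions,
    score_and_rank,
    wl_atom_features,
)
from pyrocast.synthetic_data import generate_flavour_set


def product_keys(candidates):
    return {tuple(p.canonical_smiles for p in prods) for _, prods in candidates}


# ---------------------------------------------------------------------------
# feature vectors

def test_atom_features_pentanedione_carbonyl(pentanedione):
    raw, agg = wl_atom_features(pentanedione)
    carbonyl = raw[2]  # CCC(=O)C(=O)C -> atom 2 is the first carbonyl carbon
    assert carbonyl.atomic_number == 6
    assert carbonyl.degree == 3
    assert carbonyl.total_valence == 4
    assert carbonyl.formal_charge == 0
    assert not carbonyl.aromatic
    # neighbor aggregation adds the three neighbors' raw vectors
    expected = raw[2].as_array() + raw[1].as_array() + raw[3].as_array() + raw[4].as_array()
    assert agg[2] == pytest.approx(expected)


def test_atom_features_water_and_benzene():
    raw, _ = wl_atom_features(parse_molecule("O"))
    assert raw[0].degree == 0 and raw[0].total_valence == 2
    raw, _ = wl_atom_features(parse_molecule("c1ccccc1"))
    assert all(f.aromatic for f in raw)
    feats = bond_features(parse_molecule("c1ccccc1"))
    assert all(f.bond_order == 1.5 and f.in_ring for f in feats)


# ---------------------------------------------------------------------------
# edit-set invariants

def test_bond_edit_validation():
    with pytest.raises(ValueError):
        BondEdit(3, 1, 1, 0)            # atom_i >= atom_j
    with pytest.raises(ValueError):
        BondEdit(1, 2, 1, 1)            # no change
    with pytest.raises(ValueError):
        EditSet(edits=())               # empty
    e = BondEdit(0, 1, 1, 0, "C", "H")
    with pytest.raises(ValueError):
        EditSet(edits=(e,) * 6)         # > 5 edits
    with pytest.raises(ValueError):
        EditSet(edits=(e, BondEdit(0, 1, 1, 2, "C", "H")))  # duplicate pair
    assert EditSet(edits=(e,)).hydrogen_edits == (e,)


# ---------------------------------------------------------------------------
# enumeration

def test_methane_has_no_single_edit_chemistry():
    assert enumerate_candidate_reactions(parse_molecule("C"), max_changes=1) == []


def test_ethane_dehydrogenation_found():
    keys = product_keys(enumerate_candidate_reactions(parse_molecule("CC"),
                                                      max_changes=5))
    assert ("C=C", "[H][H]") in keys


def test_ethyl_acetate_contains_all_three_elimination_pathways():
    keys = product_keys(enumerate_candidate_reactions(
        parse_molecule("CCOC(C)=O"), max_changes=5))
    assert ("C=C", "CC(=O)O") in keys        # acid + alkene
    assert ("C=C=O", "CCO") in keys          # ketene + alcohol
    assert ("CC=O", "CC=O") in keys          # two carbonyls


def test_candidates_deduplicated_by_product_multiset(pentanedione):
    cands = enumerate_candidate_reactions(pentanedione, max_changes=4)
    keys = [tuple(p.canonical_smiles for p in prods) for _, prods in cands]
    assert len(keys) == len(set(keys))


def test_formula_conservation_on_synthetic_molecules():
    for mol in generate_flavour_set(40, seed=17):
        want = Counter(mol.formula)
        for edit_set, products in enumerate_candidate_reactions(mol, max_changes=4):
            got = Counter()
            for p in products:
                got.update(p.formula)
            assert got == want, edit_set.summary()


def test_raising_max_changes_only_adds_candidates():
    for smiles in ("CCOC(C)=O", "CCC(=O)C(=O)C", "CCCO"):
        mol = parse_molecule(smiles)
        keys = [product_keys(enumerate_candidate_reactions(mol, max_changes=k))
                for k in (3, 4, 5)]
        assert keys[0] <= keys[1] <= keys[2]


def test_radical_flag_admits_homolysis():
    cands = enumerate_candidate_reactions(parse_molecule("CC"), max_changes=1,
                                          allow_radicals=True)
    assert ("[CH3]", "[CH3]") in product_keys(cands)
    # default keeps valence-complete products only
    assert enumerate_candidate_reactions(parse_molecule("CC"), max_changes=1) == []


# ---------------------------------------------------------------------------
# independent brute-force oracle
#
# Enumerate ALL assignments of new bond orders to <= n_edits atom pairs of
# the explicit-H graph and keep those where every atom retains its reactant
# valence; compare product multisets with the implementation.

def _oracle_product_multisets(smiles: str, n_edits: int) -> set:
    rdmol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    Chem.Kekulize(rdmol, clearAromaticFlags=True)
    n = rdmol.GetNumAtoms()
    symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
    bonds = {}
    for b in rdmol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bonds[(i, j)] = int(b.GetBondTypeAsDouble())
    target = [0] * n
    for (i, j), o in bonds.items():
        target[i] += o
        target[j] += o
    pairs = list(itertools.combinations(range(n), 2))
    reactant_smiles = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
    found = set()
    for k in range(1, n_edits + 1):
        for chosen in itertools.combinations(pairs, k):
            order_options = []
            for pair in chosen:
                old = bonds.get(pair, 0)
                order_options.append([o for o in range(4) if o != old])
            for new_orders in itertools.product(*order_options):
                state = dict(bonds)
                for pair, new in zip(chosen, new_orders):
                    state.pop(pair, None)
                    if new:
                        state[pair] = new
                ok = True
                degree = [0] * n
                for (i, j), o in state.items():
                    degree[i] += o
                    degree[j] += o
                if degree != target:
                    continue
                rw = Chem.RWMol()
                for sym in symbols:
                    a = Chem.Atom(sym)
                    a.SetNoImplicit(True)
                    rw.AddAtom(a)
                bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                      3: Chem.BondType.TRIPLE}
                for (i, j), o in state.items():
                    rw.AddBond(i, j, bt[o])
                try:
                    prod = rw.GetMol()
                    Chem.SanitizeMol(prod)
                except Exception:
                    ok = False
                if not ok:
                    continue
                frags = Chem.GetMolFrags(prod, asMols=True, sanitizeFrags=True)
                key = tuple(sorted(Chem.MolToSmiles(Chem.RemoveHs(f))
                                   for f in frags))
                if key != (reactant_smiles,):
                    found.add(key)
    return found


@pytest.mark.parametrize("smiles", ["CC", "CO", "C=C", "CC=O", "OCO", "C#C"])
def test_bruteforce_oracle_equivalence_two_edits(smiles):
    """At <= 2 edits no radical-free chemistry exists; both routes agree."""
    impl = product_keys(enumerate_candidate_reactions(
        parse_molecule(smiles), max_changes=2, max_break_sites=999))
    assert impl == _oracle_product_multisets(smiles, 2) == set()


@pytest.mark.parametrize("smiles", ["CC", "CO", "C=C", "CC=O", "CCO"])
def test_bruteforce_oracle_equivalence_four_edits(smiles):
    impl = product_keys(enumerate_candidate_reactions(
        parse_molecule(smiles), max_changes=4, max_break_sites=999))
    assert impl == _oracle_product_multisets(smiles, 4)


# ---------------------------------------------------------------------------
# scoring and ranking

def test_baseline_scorer_single_cc_break():
    edit = EditSet(edits=(BondEdit(0, 1, 1, 0, "C", "C"),))
    assert baseline_bond_energy_scorer(None, edit, ()) == pytest.approx(-347.0)
    assert baseline_bond_energy_scorer(None, None, ()) == 0.0


def test_bond_energy_fallback_for_unknown_pair(caplog):
    assert bond_energy("C", "F", 1) == 300.0  # order-1 default


def test_score_and_rank_orders_and_caps(pentanedione):
    cands = enumerate_candidate_reactions(pentanedione, max_changes=4)
    ranked = score_and_rank(pentanedione, cands, top_k=25)
    assert [p.rank for p in ranked] == list(range(1, len(ranked) + 1))
    scores = [p.score for p in ranked]
    assert scores == sorted(scores, reverse=True)
    assert len(ranked) <= 25
    top3 = score_and_rank(pentanedione, cands, top_k=3)
    assert len(top3) == 3 and top3 == ranked[:3]


def test_ranking_permutation_stable(pentanedione):
    cands = enumerate_candidate_reactions(pentanedione, max_changes=4)
    baseline = score_and_rank(pentanedione, cands, top_k=25)
    shuffled = cands[:]
    random.Random(7).shuffle(shuffled)
    assert score_and_rank(pentanedione, shuffled, top_k=25) == baseline


def test_equal_scores_tie_break_lexicographically(pentanedione):
    cands = enumerate_candidate_reactions(pentanedione, max_changes=4)
    ranked = score_and_rank(pentanedione, cands, scorer=lambda r, e, p: 0.0,
                            top_k=len(cands))
    keys = [tuple(m.canonical_smiles for m in p.products) for p in ranked]
    assert keys == sorted(keys)


def test_nonfinite_score_raises(pentanedione):
    cands = enumerate_candidate_reactions(pentanedione, max_changes=4)
    with pytest.raises(ScorerError):
        score_and_rank(pentanedione, cands, scorer=lambda r, e, p: float("nan"))


def test_fewer_candidates_than_top_k():
    mol = parse_molecule("CC")
    cands = enumerate_candidate_reactions(mol, max_changes=4)
    ranked = score_and_rank(mol, cands, top_k=25)
    assert len(ranked) == len(cands) < 25


# ---------------------------------------------------------------------------
# acetate pathway templates

def test_ethyl_acetate_pathways():
    out = acetate_pathway_templates(parse_molecule("CCOC(C)=O"))
    assert tuple(m.canonical_smiles for m in out["A"]) == ("C=C", "CC(=O)O")
    assert tuple(m.canonical_smiles for m in out["B"]) == ("C=C=O", "CCO")
    assert tuple(m.canonical_smiles for m in out["C"]) == ("CC=O", "CC=O")


def test_phenyl_acetate_lacks_beta_hydrogen_pathways():
    out = acetate_pathway_templates(parse_molecule("CC(=O)Oc1ccccc1"))
    assert out["A"] is None          # no sp3 alkoxy carbon / beta-H
    assert out["C"] is None          # no H on the alkoxy carbon
    assert tuple(m.canonical_smiles for m in out["B"]) == \
        ("C=C=O", "Oc1ccccc1")       # ketene + phenol


def test_pathway_products_conserve_formula():
    ester = parse_molecule("CCCCOC(C)=O")  # butyl acetate
    want = Counter(ester.formula)
    for products in acetate_pathway_templates(ester).values():
        if products is None:
            continue
        got = Counter()
        for p in products:
            got.update(p.formula)
        assert got == want


def test_non_acetate_is_domain_error():
    with pytest.raises(AcetateDomainError):
        acetate_pathway_templates(parse_molecule("CCO"))
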