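"""Synthetic flavours, spectra and hazard tables with known ground truth.

The generator emulates the study conditions the pipeline is built for:

* volatile organic flavour molecules (MW clipped to 80-250 Da, mean near
  ~150) drawn from a fragment grammar over acyl/alkoxy/alkyl/aryl pieces
  with functional-class proportions of roughly 37 % esters, 26 %
  ketones/aldehydes, 15 % alcohols/acetals, 14 % aromatics/heterocycles
  and 8 % acids/amides;
* EI-MS-like spectra whose signal peaks sit at the nominal mass keys of
  *planted* true pyrolysis products (relative abundance 10-100 %) on top
  of a sub-5 % floor of decoy peaks;
* GHS lookup fragments whose categories are drawn over the five report
  buckets (multinomial 11/13/19/49/8 %).

Two generator guarantees make end-to-end recovery provable rather than
lucky: decoy peaks never collide with the nominal mass key of *any*
enumerable candidate product (resampled on collision), and planted
products are restricted to candidates whose mass key is unique within
the ranked candidate set (structural isomers at one nominal mass cannot
be told apart by unit-mass matching, so they are not planted).  Every
case regenerates bit-identically from its seed.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass

from .chem_core import Molecule, average_mass, exact_mass, inchikey, parse_molecule, \
    round_half_away
from .ms_spectra import Spectrum, spectrum_from_pairs, write_jcamp
from .nn_ms_matching import mass_key
from .pyrolysis_enum import (
    DEFAULT_MAX_BREAK_SITES,
    DEFAULT_TOP_K,
    PyrolysisPrediction,
    enumerate_candidate_reactions,
    score_and_rank,
)

__all__ = [
    "SyntheticCase",
    "generate_flavour_set",
    "simulate_spectrum",
    "make_case",
    "write_case_files",
    "CLASS_PROPORTIONS",
    "CATEGORY_PROBS",
]

# functional-class sampling proportions (ester, ketone/aldehyde,
# alcohol/acetal, aromatic/heterocycle, acid/amide)
CLASS_PROPORTIONS = (0.37, 0.26, 0.15, 0.14, 0.08)
_CLASSES = ("ester", "ketone", "alcohol", "aromatic", "acid")

# hazard-category sampling probabilities (acute toxic, health hazard,
# irritant, other, not found)
CATEGORY_PROBS = (0.11, 0.13, 0.19, 0.49, 0.08)
_CATEGORIES = ("acute_toxic", "health_hazard", "irritant", "other", "not_found")

_CATEGORY_CONTENT = {
    "acute_toxic": (["Acute Toxic", "Irritant"], [("H330", "fatal if inhaled")]),
    "health_hazard": (["Health Hazard"], [("H350", "may cause cancer")]),
    "irritant": (["Irritant"], [("H315", "causes skin irritation")]),
    "other": (["Flammable"], [("H225", "highly flammable liquid and vapour")]),
}

_MW_RANGE = (80.0, 250.0)

_ALKYL = ("C", "CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CCC(C)C", "CCCCCC",
          "CCCCC(C)C", "CCCCCCC")
_ARYL = (
    "Cc1ccccc1", "CCc1ccccc1", "COc1ccccc1", "CC(=O)c1ccccc1", "Cc1ccncc1",
    "CC(=O)c1ccco1", "Cc1ccc(C)cc1", "CCc1cccnc1", "Cc1cnccn1", "CCOc1ccccc1",
)


def _sample_smiles(rng: random.Random, cls: str) -> str:
    a = rng.choice(_ALKYL)
    b = rng.choice(_ALKYL)
    if cls == "ester":
        return f"{a}C(=O)O{b}"
    if cls == "ketone":
        return f"{a}C(=O){b}" if rng.random() < 0.6 else f"{a}CC=O"
    if cls == "alcohol":
        if rng.random() < 0.7:
            return f"{a}C({b})O" if rng.random() < 0.5 else f"{a}CO"
        c = rng.choice(_ALKYL)
        return f"{a}C(O{b})O{c}"  # acetal
    if cls == "aromatic":
        return rng.choice(_ARYL)
    if cls == "acid":
        return f"{a}C(=O)O" if rng.random() < 0.7 else f"{a}C(=O)N{b}"
    raise ValueError(cls)


def generate_flavour_set(n: int, seed: int) -> list[Molecule]:
    """Sample ``n`` valence-valid flavour molecules (deterministic in seed).

    Functional-class proportions follow :data:`CLASS_PROPORTIONS`;
    molecular weight is clipped to 80-250 Da by resampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    out: list[Molecule] = []
    for _ in range(n):
        cls = rng.choices(_CLASSES, weights=CLASS_PROPORTIONS)[0]
        for _attempt in range(200):
            mol = parse_molecule(_sample_smiles(rng, cls))
            if _MW_RANGE[0] <= average_mass(mol) <= _MW_RANGE[1]:
                out.append(mol)
                break
        else:  # pragma: no cover - grammar always yields in-range molecules
            raise RuntimeError(f"could not sample an in-range {cls} molecule")
    return out


@dataclass(frozen=True)
class SyntheticCase:
    """One flavour with planted ground truth for end-to-end recovery."""

    flavour: Molecule
    flavour_id: str
    predictions: tuple[PyrolysisPrediction, ...]
    true_products: tuple[Molecule, ...]
    spectrum: Spectrum                       # normalized, unthresholded
    decoy_mzs: tuple[int, ...]
    hazard_table: dict                       # inchikey -> GHS entry
    cramer_table: dict                       # inchikey -> I/II/III
    true_categories: dict[str, str]          # product SMILES -> category
    seed: int


def simulate_spectrum(
    flavour: Molecule,
    planted_products: tuple[Molecule, ...],
    forbidden_mzs: frozenset[int],
    seed: int,
    n_decoys: int = 5,
    offset: float = 1.0,
) -> tuple[Spectrum, tuple[int, ...]]:
    """Build a spectrum containing the planted products' mass keys.

    Planted peaks get relative abundances in [10, 100] (the largest is
    pinned to 100 so normalization leaves every signal peak at or above
    any sane threshold); the molecular ion is included; decoy peaks are
    drawn below 5 % at masses outside ``forbidden_mzs`` (the mass keys of
    every enumerable candidate).  A planted product sharing the flavour's
    nominal mass is rejected: the parent-mass rule would make it
    unrecoverable by design.
    """
    parent_nominal = round_half_away(exact_mass(flavour))
    rng = random.Random(seed)
    for p in planted_products:
        if round_half_away(exact_mass(p)) == parent_nominal:
            raise ValueError(
                f"planted product {p.canonical_smiles} shares the flavour's "
                "nominal molecular mass and would be excluded by the "
                "parent-mass rule")
    intensities: dict[int, float] = {parent_nominal: rng.uniform(10, 100)}
    for p in planted_products:
        intensities[mass_key(p, offset)] = rng.uniform(10, 100)
    # pin the strongest signal peak at exactly 100 -> normalization is identity
    top = max(intensities, key=lambda k: intensities[k])
    intensities[top] = 100.0
    decoys: list[int] = []
    taken = set(intensities)
    for _ in range(n_decoys):
        for _attempt in range(200):
            mz = rng.randint(15, parent_nominal + 10)
            if mz not in forbidden_mzs and mz not in taken:
                taken.add(mz)
                intensities[mz] = rng.uniform(0.5, 4.9)
                decoys.append(mz)
                break
    spec = spectrum_from_pairs(
        intensities.items(), molecular_ion_mz=parent_nominal,
        source_id=f"synthetic:{flavour.canonical_smiles}")
    return spec, tuple(sorted(decoys))


def make_case(
    flavour: Molecule,
    flavour_id: str,
    seed: int,
    n_planted: int = 3,
    n_decoys: int = 5,
    max_changes: int = 4,
    max_break_sites: int = DEFAULT_MAX_BREAK_SITES,
    top_k: int = DEFAULT_TOP_K,
    offset: float = 1.0,
) -> SyntheticCase:
    """Plant up to ``n_planted`` recoverable products for one flavour.

    Planted products are drawn from the ranked top-``top_k`` predictions,
    excluding parent-mass products and any product whose mass key is
    shared by another distinct ranked product (unit-mass matching cannot
    separate those).  Zero eligible products is a valid case: the
    spectrum then carries only the molecular ion and decoys and the
    pipeline must return an empty match set.
    """
    rng = random.Random(seed)
    candidates = enumerate_candidate_reactions(
        flavour, max_changes=max_changes, max_break_sites=max_break_sites)
    predictions = score_and_rank(flavour, candidates, top_k=top_k)
    parent_nominal = round_half_away(exact_mass(flavour))

    all_keys = frozenset(
        mass_key(p, offset) for _, prods in candidates for p in prods
    ) | {parent_nominal}
    ranked_products = {
        p.canonical_smiles: p
        for pred in predictions for p in pred.products
    }
    key_counts = Counter(
        mass_key(p, offset) for p in ranked_products.values())
    eligible = [
        p for p in ranked_products.values()
        if key_counts[mass_key(p, offset)] == 1
        and round_half_away(exact_mass(p)) != parent_nominal
    ]
    eligible.sort(key=lambda p: p.canonical_smiles)
    planted = tuple(rng.sample(eligible, min(n_planted, len(eligible))))

    spectrum, decoys = simulate_spectrum(
        flavour, planted, all_keys, seed=rng.randrange(2**31),
        n_decoys=n_decoys, offset=offset)

    hazard_table: dict = {}
    cramer_table: dict = {}
    true_categories: dict[str, str] = {}
    for p in planted:
        cat = rng.choices(_CATEGORIES, weights=CATEGORY_PROBS)[0]
        true_categories[p.canonical_smiles] = cat
        key = inchikey(p)
        if cat != "not_found":
            pictograms, statements = _CATEGORY_CONTENT[cat]
            hazard_table[key] = {
                "pictograms": list(pictograms),
                "statements": [{"code": c, "text": t} for c, t in statements],
            }
            cramer_table[key] = rng.choice(["I", "II", "III"])
    return SyntheticCase(
        flavour=flavour, flavour_id=flavour_id, predictions=tuple(predictions),
        true_products=planted, spectrum=spectrum, decoy_mzs=decoys,
        hazard_table=hazard_table, cramer_table=cramer_table,
        true_categories=true_categories, seed=seed)


def write_case_files(cases: list[SyntheticCase], out_dir) -> None:
    """Write cases in the formats the pipeline reads (.smi, JCAMP, JSON).

    Round-trip guarantee: reading these files back reproduces each case's
    flavour, spectrum and hazard table exactly.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    with open(out / "flavours.smi", "w") as fh:
        for case in cases:
            fh.write(f"{case.flavour.canonical_smiles}\t{case.flavour_id}\n")
    ghs: dict = {}
    cramer: dict = {}
    for case in cases:
        with open(out / "spectra" / f"{case.flavour_id}.jdx", "w") as fh:
            fh.write(write_jcamp(case.spectrum, title=case.flavour_id))
        ghs.update(case.hazard_table)
        cramer.update(case.cramer_table)
    with open(out / "ghs_lookup.json", "w") as fh:
        json.dump(ghs, fh, indent=1, sort_keys=True)
    with open(out / "cramer_lookup.json", "w") as fh:
        json.dump(cramer, fh, indent=1, sort_keys=True)
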