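"""Activation-energy estimation scaffolding and its accuracy metric.

Pyrolysis activation energies (AE, kcal/mol) let the elimination pathways
of a flavour be compared: the lowest-AE route is the one expected to
dominate under heating.  Quantitative AE prediction belongs to a trained
model; this module fixes the surrounding contracts so one can plug in:

* the ``AEEstimator`` interface (reactant + products -> AE, sd);
* a crude additive baseline (sum of mean enthalpies of bonds broken minus
  bonds formed, floored at 0) — a thermochemical stand-in, explicitly
  non-quantitative and blind to transition-state effects;
* the RMSE accuracy metric and a generic k-fold train/validation/test
  harness for evaluating estimators.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from rdkit import Chem

from .chem_core import Molecule
from .pyrolysis_enum import acetate_pathway_templates, bond_energy

__all__ = [
    "AEPrediction",
    "AEEstimator",
    "rmse",
    "additive_bond_energy_estimator",
    "compare_pathways",
    "cross_validate_estimator",
    "KJ_PER_KCAL",
]

KJ_PER_KCAL = 4.184


@dataclass(frozen=True)
class AEPrediction:
    reactant: Molecule
    products: tuple[Molecule, ...]
    ae_kcal_per_mol: float
    sd: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.ae_kcal_per_mol):
            raise ValueError("activation energy must be finite")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


class AEEstimator(Protocol):
    def __call__(self, reactant: Molecule,
                 products: tuple[Molecule, ...]) -> tuple[float, float]:
        """Return (AE in kcal/mol, standard deviation)."""


def rmse(y: Sequence[float], z: Sequence[float]) -> float:
    """Root mean square error sqrt(1/N * sum((y_i - z_i)^2)).

    Zero iff the vectors are identical; raises on length mismatch.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape or y.ndim != 1 or y.size == 0:
        raise ValueError(
            f"rmse needs two equal-length nonempty vectors, got {y.shape} vs {z.shape}")
    return float(np.sqrt(np.mean((y - z) ** 2)))


def _bond_multiset(mol: Molecule) -> Counter:
    molh = Chem.AddHs(mol.rdmol)
    Chem.Kekulize(molh, clearAromaticFlags=True)
    counts: Counter = Counter()
    for b in molh.GetBonds():
        pair = tuple(sorted((b.GetBeginAtom().GetSymbol(), b.GetEndAtom().GetSymbol())))
        counts[(pair, int(b.GetBondTypeAsDouble()))] += 1
    return counts


def additive_bond_energy_estimator(
    reactant: Molecule, products: tuple[Molecule, ...],
    table: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Baseline AE: max(0, sum E(bonds broken) - sum E(bonds formed)).

    Computed from the bond-multiset difference between reactant and
    products with mean bond enthalpies, converted to kcal/mol.  This is
    reaction enthalpy, not a barrier: endothermic steps get their
    endothermicity as a floor and every exothermic or thermoneutral step
    collapses to 0.  Useful as a deterministic placeholder only.
    """
    before = _bond_multiset(reactant)
    after: Counter = Counter()
    for p in products:
        after.update(_bond_multiset(p))
    delta_kj = 0.0
    for (pair, order), n in (before - after).items():
        delta_kj += n * bond_energy(pair[0], pair[1], order, table)
    for (pair, order), n in (after - before).items():
        delta_kj -= n * bond_energy(pair[0], pair[1], order, table)
    return max(0.0, delta_kj / KJ_PER_KCAL), 0.0


@dataclass(frozen=True)
class PathwayComparison:
    predictions: dict[str, AEPrediction | None]   # None: pathway not applicable
    unavailable: tuple[str, ...]                  # estimator failed
    lowest: tuple[str, ...]                       # argmin pathways (ties reported)


def compare_pathways(ester: Molecule, estimator: AEEstimator) -> PathwayComparison:
    """Estimate AE for the acetate elimination pathways A/B/C of ``ester``.

    Not-applicable pathways carry no value; an estimator failure marks
    that pathway unavailable without hiding the others.  The ``lowest``
    field lists every pathway tied at the minimum AE.
    """
    templates = acetate_pathway_templates(ester)  # raises on non-acetates
    predictions: dict[str, AEPrediction | None] = {}
    unavailable: list[str] = []
    for pathway, products in templates.items():
        if products is None:
            predictions[pathway] = None
            continue
        try:
            ae, sd = estimator(ester, products)
            predictions[pathway] = AEPrediction(
                reactant=ester, products=products, ae_kcal_per_mol=ae, sd=sd)
        except Exception:
            unavailable.append(pathway)
            predictions[pathway] = None
    values = {p: pred.ae_kcal_per_mol for p, pred in predictions.items()
              if pred is not None}
    lowest: tuple[str, ...] = ()
    if values:
        vmin = min(values.values())
        lowest = tuple(sorted(p for p, v in values.items() if v == vmin))
    return PathwayComparison(predictions=predictions,
                             unavailable=tuple(unavailable), lowest=lowest)


def cross_validate_estimator(
    examples: Sequence[tuple],
    fit_predict: Callable,
    n_folds: int = 10,
    fractions: tuple[float, float, float] = (0.85, 0.05, 0.10),
    seed: int = 0,
) -> dict:
    """Generic k-fold evaluation harness with train/validation/test splits.

    Each fold reshuffles the examples and splits them into the given
    fractions; ``fit_predict(train, val, test)`` must return predicted AE
    values for the test examples, whose true values are each example's
    last element.  Returns per-fold RMSEs with their mean and sd.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if len(examples) < n_folds:
        raise ValueError("need at least one example per fold")
    rng = np.random.default_rng(seed)
    examples = list(examples)
    fold_rmses = []
    n = len(examples)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    for _ in range(n_folds):
        idx = rng.permutation(n)
        train = [examples[i] for i in idx[:n_train]]
        val = [examples[i] for i in idx[n_train:n_train + n_val]]
        test = [examples[i] for i in idx[n_train + n_val:]]
        preds = fit_predict(train, val, test)
        truth = [ex[-1] for ex in test]
        fold_rmses.append(rmse(truth, preds))
    arr = np.array(fold_rmses)
    return {"fold_rmse": fold_rmses, "mean_rmse": float(arr.mean()),
            "sd_rmse": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0}
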