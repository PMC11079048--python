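"""GHS hazard aggregation and per-flavour risk reports.

Each matched pyrolysis product is assigned exactly one hazard category by
severity precedence over its GHS pictogram keywords:

    acute_toxic (i) > health_hazard (ii) > irritant (iii) > other (iv),

with ``not_found`` (v) for compounds absent from the lookup table.
Inhalation-relevant hazard statements (H330, H331, H335, H340, H341,
H350, H373 by default) are extracted separately, since lung exposure is
the route of concern for vaped aerosols.  Cramer classes (I low / II
moderate / III high expected oral toxicity) come from a lookup adapter;
the decision tree itself is external prediction software's job.

Lookups are local JSON tables keyed by InChIKey; a live database adapter
can implement the same callable interface.
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Callable

from .chem_core import Molecule, inchikey
from .nn_ms_matching import MatchSet
from .pyrolysis_enum import PyrolysisPrediction

logger = logging.getLogger(__name__)

__all__ = [
    "GHSRecord",
    "HazardCategory",
    "FlavourRiskReport",
    "assign_ghs_category",
    "extract_inhalation_statements",
    "build_flavour_report",
    "load_ghs_lookup",
    "load_cramer_lookup",
    "category_tally",
    "INHALATION_H_CODES",
]

_H_CODE_RE = re.compile(r"^H\d{3}$")

#: inhalation-relevant GHS hazard statements (configurable set)
INHALATION_H_CODES = ("H330", "H331", "H335", "H340", "H341", "H350", "H373")

#: pictogram keyword (lower-cased) -> category bucket
_PICTOGRAM_MAP = {
    "acute toxic": "acute_toxic",
    "health hazard": "health_hazard",
    "irritant": "irritant",
}


class HazardCategory(enum.Enum):
    """The five report buckets, most serious first."""

    ACUTE_TOXIC = "acute_toxic"      # (i)
    HEALTH_HAZARD = "health_hazard"  # (ii)
    IRRITANT = "irritant"            # (iii)
    OTHER = "other"                  # (iv) classified, but none of the above
    NOT_FOUND = "not_found"          # (v) no database record

    @property
    def severity(self) -> int:
        return list(HazardCategory).index(self)


@dataclass(frozen=True)
class GHSRecord:
    """A compound's GHS classification snapshot from a lookup table."""

    compound_key: str                                # canonical SMILES or InChIKey
    hazard_statements: tuple[tuple[str, str], ...]   # (H-code, text)
    pictogram_keywords: tuple[str, ...]

    def __post_init__(self):
        for code, _ in self.hazard_statements:
            if not _H_CODE_RE.match(code):
                raise ValueError(f"malformed hazard statement code {code!r}")


def assign_ghs_category(rec: GHSRecord | None) -> HazardCategory:
    """Most serious applicable category; ``NOT_FOUND`` for a missing record.

    Total and order-independent in the record's keyword list.
    """
    if rec is None:
        return HazardCategory.NOT_FOUND
    buckets = {
        _PICTOGRAM_MAP[kw.strip().lower()]
        for kw in rec.pictogram_keywords
        if kw.strip().lower() in _PICTOGRAM_MAP
    }
    for cat in (HazardCategory.ACUTE_TOXIC, HazardCategory.HEALTH_HAZARD,
                HazardCategory.IRRITANT):
        if cat.value in buckets:
            return cat
    return HazardCategory.OTHER


def extract_inhalation_statements(
    rec: GHSRecord,
    inhalation_codes: tuple[str, ...] = INHALATION_H_CODES,
) -> list[str]:
    """The record's H-codes restricted to the inhalation-relevant set,
    record order preserved."""
    relevant = set(inhalation_codes)
    return [code for code, _ in rec.hazard_statements if code in relevant]


# ---------------------------------------------------------------------------
# lookup adapters (local JSON tables)

def load_ghs_lookup(source) -> Callable[[str], GHSRecord | None]:
    """Build an InChIKey -> GHSRecord lookup from a JSON table.

    Table layout: ``{inchikey: {"statements": [{"code", "text"}, ...],
    "pictograms": [...]}}``.  ``source`` is a path or an already-parsed
    dict.  Keys absent from the table map to None.
    """
    if isinstance(source, dict):
        table = source
    else:
        with open(source) as fh:
            table = json.load(fh)

    def lookup(key: str) -> GHSRecord | None:
        entry = table.get(key)
        if entry is None:
            return None
        return GHSRecord(
            compound_key=key,
            hazard_statements=tuple(
                (s["code"], s.get("text", "")) for s in entry.get("statements", [])),
            pictogram_keywords=tuple(entry.get("pictograms", [])),
        )

    return lookup


def load_cramer_lookup(source) -> Callable[[str], str | None]:
    """InChIKey -> Cramer class ("I"/"II"/"III") lookup from JSON/dict."""
    if isinstance(source, dict):
        table = source
    else:
        with open(source) as fh:
            table = json.load(fh)

    def lookup(key: str) -> str | None:
        cls = table.get(key)
        if cls is not None and cls not in ("I", "II", "III"):
            raise ValueError(f"invalid Cramer class {cls!r} for {key}")
        return cls

    return lookup


# ---------------------------------------------------------------------------
# report assembly

@dataclass(frozen=True)
class FlavourRiskReport:
    """Per-flavour bundle: predictions, matches, hazards, Cramer classes."""

    flavour_id: str
    flavour_smiles: str
    predictions: tuple[PyrolysisPrediction, ...]
    matchset: MatchSet
    product_categories: dict[str, HazardCategory]     # SMILES -> category
    inhalation_statements: dict[str, tuple[str, ...]]  # SMILES -> H-codes
    cramer_classes: dict[str, str | None]              # SMILES -> I/II/III/None
    category_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "flavour_id": self.flavour_id,
            "flavour_smiles": self.flavour_smiles,
            "n_predictions": len(self.predictions),
            "predictions": [
                {"rank": p.rank, "score": p.score,
                 "products": [m.canonical_smiles for m in p.products],
                 "edits": p.edit_set.summary()}
                for p in self.predictions
            ],
            "n_discrete_matches": self.matchset.n_discrete,
            "matches": [
                {"product": r.product.canonical_smiles, "nn_rank": r.nn_rank,
                 "matched_mz": r.matched_mz}
                for r in self.matchset.records
            ],
            "product_categories": {s: c.value
                                   for s, c in sorted(self.product_categories.items())},
            "inhalation_statements": {s: list(v) for s, v in
                                      sorted(self.inhalation_statements.items())},
            "cramer_classes": dict(sorted(self.cramer_classes.items())),
            "category_counts": self.category_counts,
        }


def build_flavour_report(
    flavour: Molecule,
    flavour_id: str,
    predictions: list[PyrolysisPrediction],
    matchset: MatchSet,
    ghs_lookup: Callable[[str], GHSRecord | None],
    cramer_lookup: Callable[[str], str | None] | None = None,
) -> FlavourRiskReport:
    """Assemble the risk report for one flavour.

    A lookup that raises is logged with the compound identified and
    treated as a missing record; the report is still produced.  Category
    counts over the five buckets always sum to the number of discrete
    matched products.
    """
    categories: dict[str, HazardCategory] = {}
    inhalation: dict[str, tuple[str, ...]] = {}
    cramer: dict[str, str | None] = {}
    by_smiles = {r.product.canonical_smiles: r.product for r in matchset.records}
    for smi in sorted(matchset.discrete_products):
        product = by_smiles[smi]
        key = inchikey(product)
        try:
            rec = ghs_lookup(key)
        except Exception as exc:
            logger.warning("GHS lookup failed for %s (%s): %s", smi, key, exc)
            rec = None
        categories[smi] = assign_ghs_category(rec)
        inhalation[smi] = tuple(extract_inhalation_statements(rec)) if rec else ()
        if cramer_lookup is not None:
            try:
                cramer[smi] = cramer_lookup(key)
            except Exception as exc:
                logger.warning("Cramer lookup failed for %s (%s): %s", smi, key, exc)
                cramer[smi] = None
        else:
            cramer[smi] = None
    counts = {cat.value: 0 for cat in HazardCategory}
    for cat in categories.values():
        counts[cat.value] += 1
    assert sum(counts.values()) == matchset.n_discrete
    return FlavourRiskReport(
        flavour_id=flavour_id,
        flavour_smiles=flavour.canonical_smiles,
        predictions=tuple(predictions),
        matchset=matchset,
        product_categories=categories,
        inhalation_statements=inhalation,
        cramer_classes=cramer,
        category_counts=counts,
    )


def category_tally(reports: list[FlavourRiskReport]) -> dict[str, int]:
    """Sum category counts across reports (matched products, per flavour)."""
    total = {cat.value: 0 for cat in HazardCategory}
    for rep in reports:
        for cat, n in rep.category_counts.items():
            total[cat] += n
    return total
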