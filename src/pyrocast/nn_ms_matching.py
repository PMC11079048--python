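"""Correlation of predicted pyrolysis products with EI-MS fragment masses.

The core matching rule: a predicted product is keyed by its monoisotopic
mass minus a fixed offset (default 1.0 Da, the charge-carrying hydrogen
an even-electron EI fragment is short of), rounded half-away-from-zero to
the nearest whole number.  A product matches a flavour's spectrum when
that key equals a retained (thresholded) peak m/z.  Products whose
rounded monoisotopic mass equals the flavour's own are excluded before
matching — a fragment peak at the parent mass is the molecular ion, not
evidence of decomposition.

Matches are counted at two granularities: per (product, rank) record, and
"discrete" per flavour (each distinct product counted once regardless of
how many ranks or peaks it matched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem_core import Molecule, exact_mass, round_half_away
from .ms_spectra import Spectrum
from .pyrolysis_enum import PyrolysisPrediction

__all__ = [
    "DEFAULT_MASS_OFFSET",
    "MatchRecord",
    "MatchSet",
    "MatchStatistics",
    "UnthresholdedSpectrumError",
    "mass_key",
    "match_flavour",
    "match_statistics",
    "product_provenance_index",
]

#: Da subtracted from the monoisotopic product mass before rounding.
DEFAULT_MASS_OFFSET = 1.0


class UnthresholdedSpectrumError(ValueError):
    """Matching against a raw spectrum would admit noise peaks."""


def mass_key(product: Molecule, offset: float = DEFAULT_MASS_OFFSET) -> int:
    """Nominal-mass key: round_half_away(exact_mass - offset)."""
    return round_half_away(exact_mass(product) - offset)


@dataclass(frozen=True)
class MatchRecord:
    flavour_id: str
    product: Molecule
    nn_rank: int            # rank of the prediction the product came from
    matched_mz: int         # retained peak the key hit
    product_mass_key: int   # == matched_mz by construction

    def __post_init__(self):
        if self.matched_mz != self.product_mass_key:
            raise ValueError("matched_mz must equal product_mass_key")


@dataclass(frozen=True)
class MatchSet:
    flavour_id: str
    records: tuple[MatchRecord, ...]
    discrete_products: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_discrete(self) -> int:
        return len(self.discrete_products)


def match_flavour(
    flavour: Molecule,
    flavour_id: str,
    predictions: list[PyrolysisPrediction],
    spec: Spectrum,
    offset: float = DEFAULT_MASS_OFFSET,
) -> MatchSet:
    """Match every predicted product's mass key against retained peaks.

    One record per (product, rank) pair that hits a peak; a product
    matching several peaks is still one record per rank.  Requires a
    thresholded spectrum.
    """
    if spec.threshold_applied is None:
        raise UnthresholdedSpectrumError(
            f"spectrum {spec.source_id!r} has no abundance threshold applied")
    parent_nominal = round_half_away(exact_mass(flavour))
    peak_mzs = spec.mz_set
    records: list[MatchRecord] = []
    seen: set[tuple[str, int]] = set()
    for pred in predictions:
        for product in pred.products:
            if round_half_away(exact_mass(product)) == parent_nominal:
                continue  # parent-mass rule: same MW as the molecular ion
            key = mass_key(product, offset)
            if key in peak_mzs and (product.canonical_smiles, pred.rank) not in seen:
                seen.add((product.canonical_smiles, pred.rank))
                records.append(MatchRecord(
                    flavour_id=flavour_id, product=product, nn_rank=pred.rank,
                    matched_mz=key, product_mass_key=key))
    return MatchSet(
        flavour_id=flavour_id,
        records=tuple(records),
        discrete_products=frozenset(r.product.canonical_smiles for r in records),
    )


@dataclass(frozen=True)
class MatchStatistics:
    """Aggregate match/rank statistics over a set of flavours.

    ``rank_histogram`` counts every record; ``rank_histogram_discrete``
    counts each discrete product once at its best (lowest) rank — both are
    kept because per-rank plots can be drawn either way.  The rank shares
    (rank-1, ranks 1-5, ranks top_k-4..top_k) are fractions of all
    records.
    """

    n_flavours: int
    mean_discrete_matches_per_flavour: float
    frac_at_least_one: float
    frac_more_than_one: float
    rank_histogram: dict[int, int]
    rank_histogram_discrete: dict[int, int]
    rank1_share: float
    top5_share: float
    bottom5_share: float


def match_statistics(matchsets: list[MatchSet], top_k: int) -> MatchStatistics:
    """Compute the headline statistics over per-flavour match sets."""
    if not matchsets:
        raise ValueError("match_statistics requires at least one MatchSet")
    n = len(matchsets)
    discrete_counts = [ms.n_discrete for ms in matchsets]
    hist: dict[int, int] = {}
    hist_discrete: dict[int, int] = {}
    total_records = 0
    for ms in matchsets:
        best_rank: dict[str, int] = {}
        for rec in ms.records:
            hist[rec.nn_rank] = hist.get(rec.nn_rank, 0) + 1
            total_records += 1
            smi = rec.product.canonical_smiles
            best_rank[smi] = min(best_rank.get(smi, rec.nn_rank), rec.nn_rank)
        for rank in best_rank.values():
            hist_discrete[rank] = hist_discrete.get(rank, 0) + 1

    def share(ranks) -> float:
        if total_records == 0:
            return 0.0
        return sum(hist.get(r, 0) for r in ranks) / total_records

    return MatchStatistics(
        n_flavours=n,
        mean_discrete_matches_per_flavour=sum(discrete_counts) / n,
        frac_at_least_one=sum(c >= 1 for c in discrete_counts) / n,
        frac_more_than_one=sum(c > 1 for c in discrete_counts) / n,
        rank_histogram=dict(sorted(hist.items())),
        rank_histogram_discrete=dict(sorted(hist_discrete.items())),
        rank1_share=share([1]),
        top5_share=share(range(1, 6)),
        bottom5_share=share(range(top_k - 4, top_k + 1)),
    )


def product_provenance_index(matchsets: list[MatchSet]) -> dict[str, list[str]]:
    """Inverse index: matched product SMILES -> sorted unique flavour ids.

    Answers "which flavours can produce compound X" (e.g. mapping a
    volatile carbonyl back to every flavour predicted to generate it).
    """
    index: dict[str, set[str]] = {}
    for ms in matchsets:
        for smi in ms.discrete_products:
            index.setdefault(smi, set()).add(ms.flavour_id)
    return {smi: sorted(ids) for smi, ids in sorted(index.items())}
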