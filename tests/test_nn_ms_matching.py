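import pytest

from pyrocast.chem_core import parse_molecule
from pyrocast.ms_spectra import apply_threshold, spectrum_from_pairs
from pyrocast.nn_ms_matching import (
    MatchRecord,
    MatchSet,
    UnthresholdedSpectrumError,
    mass_key,
    match_flavour,
    match_statistics,
    product_provenance_index,
)
from pyrocast.pyrolysis_enum import PyrolysisPrediction


def toy_predictions(*smiles_groups):
    return [
        PyrolysisPrediction(rank=i, score=float(-i), edit_set=None,
                            products=tuple(parse_molecule(s) for s in group))
        for i, group in enumerate(smiles_groups, start=1)
    ]


@pytest.mark.parametrize("smiles, key", [
    ("CC=O", 43),   # acetaldehyde, 44.0262 - 1 -> 43
    ("O", 17),      # water, 18.0106 - 1 -> 17
    ("C", 15),      # methane, 16.0313 - 1 -> 15
])
def test_mass_key_subtract_one_and_round(smiles, key):
    assert mass_key(parse_molecule(smiles)) == key


def test_pentanedione_toy_matching(pentanedione, pentanedione_spectrum):
    """Acetaldehyde and methane hit printed peaks 43 and 15; water (17) misses."""
    spec = apply_threshold(pentanedione_spectrum, 5.0)
    preds = toy_predictions(["CC=O"], ["C"], ["O"])
    ms = match_flavour(pentanedione, "pentanedione", preds, spec)
    assert {r.matched_mz for r in ms.records} == {43, 15}
    assert ms.discrete_products == {"CC=O", "C"}
    for r in ms.records:
        assert r.matched_mz == r.product_mass_key  # defining invariant


def test_parent_mass_products_excluded(pentanedione, pentanedione_spectrum):
    spec = apply_threshold(pentanedione_spectrum, 5.0)
    # an isomerization product with the flavour's own formula C5H8O2; its
    # key (99) is not the point - the parent-mass rule must drop it first
    isomer = "CC(=O)CCC=O"
    preds = toy_predictions([isomer])
    ms = match_flavour(pentanedione, "pentanedione", preds, spec)
    assert ms.records == ()


def test_empty_predictions_empty_matchset(pentanedione, pentanedione_spectrum):
    spec = apply_threshold(pentanedione_spectrum, 5.0)
    ms = match_flavour(pentanedione, "pentanedione", [], spec)
    assert ms.records == () and ms.n_discrete == 0


def test_unthresholded_spectrum_rejected(pentanedione, pentanedione_spectrum):
    with pytest.raises(UnthresholdedSpectrumError):
        match_flavour(pentanedione, "pentanedione",
                      toy_predictions(["C"]), pentanedione_spectrum)


def test_product_counted_once_per_rank(pentanedione, pentanedione_spectrum):
    spec = apply_threshold(pentanedione_spectrum, 5.0)
    # methane appears at two ranks -> two records, one discrete product
    ms = match_flavour(pentanedione, "p", toy_predictions(["C"], ["C", "CC=O"]), spec)
    assert len(ms.records) == 3
    assert ms.discrete_products == {"C", "CC=O"}


def test_removing_a_peak_never_increases_matches(pentanedione, pentanedione_spectrum):
    preds = toy_predictions(["CC=O"], ["C"], ["O"])
    full = apply_threshold(pentanedione_spectrum, 5.0)
    n_full = len(match_flavour(pentanedione, "p", preds, full).records)
    reduced = spectrum_from_pairs(
        [(p.mz, p.rel_abundance) for p in full.peaks if p.mz != 15],
        threshold_applied=5.0)
    n_reduced = len(match_flavour(pentanedione, "p", preds, reduced).records)
    assert n_reduced <= n_full
    assert n_reduced == n_full - 1  # exactly the methane match disappears


def _matchset(flavour_id, *records):
    return MatchSet(flavour_id=flavour_id, records=tuple(records),
                    discrete_products=frozenset(
                        r.product.canonical_smiles for r in records))


def _record(flavour_id, smiles, rank):
    product = parse_molecule(smiles)
    key = mass_key(product)
    return MatchRecord(flavour_id=flavour_id, product=product, nn_rank=rank,
                       matched_mz=key, product_mass_key=key)


def test_match_statistics_arithmetic():
    sets = [
        _matchset("a", _record("a", "C", 1), _record("a", "CC", 2)),
        _matchset("b"),
        _matchset("c", _record("c", "C", 1)),
    ]
    stats = match_statistics(sets, top_k=25)
    assert stats.mean_discrete_matches_per_flavour == pytest.approx(1.0)
    assert stats.frac_at_least_one == pytest.approx(2 / 3)
    assert stats.frac_more_than_one == pytest.approx(1 / 3)
    assert stats.rank_histogram == {1: 2, 2: 1}
    assert sum(stats.rank_histogram.values()) == 3
    assert stats.rank1_share == pytest.approx(2 / 3)
    assert stats.top5_share == pytest.approx(1.0)
    assert stats.bottom5_share == 0.0


def test_all_rank_one_matches():
    sets = [_matchset("a", _record("a", "C", 1))]
    assert match_statistics(sets, top_k=25).rank1_share == 1.0


def test_match_statistics_requires_input():
    with pytest.raises(ValueError):
        match_statistics([], top_k=25)


def test_discrete_histogram_uses_best_rank():
    sets = [_matchset("a", _record("a", "C", 3), _record("a", "C", 1))]
    stats = match_statistics(sets, top_k=25)
    assert stats.rank_histogram == {1: 1, 3: 1}
    assert stats.rank_histogram_discrete == {1: 1}


def test_provenance_index():
    sets = [
        _matchset("a", _record("a", "CC", 1)),
        _matchset("b", _record("b", "CC", 2), _record("b", "C", 1)),
    ]
    index = product_provenance_index(sets)
    assert index["CC"] == ["a", "b"]
    assert index["C"] == ["b"]
    assert product_provenance_index([]) == {}
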