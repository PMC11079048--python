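import itertools

import pytest

from pyrocast.chem_core import parse_molecule, inchikey
from pyrocast.hazard_profile import (
    GHSRecord,
    HazardCategory,
    assign_ghs_category,
    build_flavour_report,
    category_tally,
    extract_inhalation_statements,
    load_cramer_lookup,
    load_ghs_lookup,
)
from pyrocast.ms_spectra import apply_threshold
from pyrocast.nn_ms_matching import match_flavour
from pyrocast.pipeline import run_cases


def record(pictograms=(), statements=()):
    return GHSRecord(compound_key="X", pictogram_keywords=tuple(pictograms),
                     hazard_statements=tuple((c, "") for c in statements))


def test_most_serious_classification_wins():
    rec = record(["Irritant", "Acute Toxic"])
    assert assign_ghs_category(rec) is HazardCategory.ACUTE_TOXIC
    rec = record(["Irritant", "Health Hazard"])
    assert assign_ghs_category(rec) is HazardCategory.HEALTH_HAZARD


def test_other_and_not_found_buckets():
    assert assign_ghs_category(record(["Flammable", "Compressed Gas"])) \
        is HazardCategory.OTHER
    assert assign_ghs_category(record()) is HazardCategory.OTHER
    assert assign_ghs_category(None) is HazardCategory.NOT_FOUND


def test_category_assignment_is_total_and_order_independent():
    keywords = ["Acute Toxic", "Health Hazard", "Irritant", "Flammable"]
    for n in range(len(keywords) + 1):
        for subset in itertools.combinations(keywords, n):
            cats = {assign_ghs_category(record(perm))
                    for perm in itertools.permutations(subset)}
            assert len(cats) == 1  # order never changes the outcome


@pytest.mark.parametrize("codes, expected", [
    (("H330", "H225"), ["H330"]),
    ((), []),
    (("H350",), ["H350"]),
    (("H335", "H341", "H301"), ["H335", "H341"]),
])
def test_inhalation_statement_extraction(codes, expected):
    assert extract_inhalation_statements(record(statements=codes)) == expected


def test_malformed_h_code_rejected():
    with pytest.raises(ValueError):
        record(statements=("H33",))
    with pytest.raises(ValueError):
        record(statements=("X330",))


def _toy_report(lookup, cramer=None):
    from pyrocast.synthetic_data import make_case

    flavour = parse_molecule("CCC(=O)C(=O)C")
    case = make_case(flavour, "pentanedione", seed=1, n_planted=2)
    spec = apply_threshold(case.spectrum, 5.0)
    matchset = match_flavour(flavour, "pentanedione", list(case.predictions), spec)
    return matchset, build_flavour_report(
        flavour, "pentanedione", list(case.predictions), matchset, lookup, cramer)


def test_report_tallies_sum_to_discrete_matches():
    acute_key = None
    flavour = parse_molecule("CCC(=O)C(=O)C")

    def lookup(key):
        nonlocal acute_key
        if acute_key is None:
            acute_key = key  # first product looked up becomes acute toxic
        if key == acute_key:
            return GHSRecord(compound_key=key,
                             pictogram_keywords=("Acute Toxic",),
                             hazard_statements=(("H330", "fatal if inhaled"),))
        return None

    matchset, report = _toy_report(lookup)
    assert matchset.n_discrete == 2
    assert report.category_counts["acute_toxic"] == 1
    assert report.category_counts["not_found"] == 1
    assert sum(report.category_counts.values()) == matchset.n_discrete
    assert report.to_dict()["n_discrete_matches"] == 2


def test_failing_lookup_is_isolated_not_fatal():
    def lookup(key):
        raise RuntimeError("database down")

    matchset, report = _toy_report(lookup)
    assert all(c is HazardCategory.NOT_FOUND
               for c in report.product_categories.values())


def test_empty_matchset_gives_zero_tallies(pentanedione, pentanedione_spectrum):
    spec = apply_threshold(pentanedione_spectrum, 5.0)
    matchset = match_flavour(pentanedione, "p", [], spec)
    report = build_flavour_report(pentanedione, "p", [], matchset,
                                  lambda key: None, None)
    assert sum(report.category_counts.values()) == 0


def test_lookup_adapters_roundtrip(tmp_path):
    import json

    mol = parse_molecule("CC=O")
    key = inchikey(mol)
    ghs = {key: {"pictograms": ["Irritant"],
                 "statements": [{"code": "H319", "text": "eye irritation"}]}}
    cramer = {key: "III"}
    ghs_path = tmp_path / "ghs.json"
    ghs_path.write_text(json.dumps(ghs))
    lookup = load_ghs_lookup(ghs_path)
    rec = lookup(key)
    assert rec.pictogram_keywords == ("Irritant",)
    assert lookup("MISSINGKEY") is None
    assert load_cramer_lookup(cramer)(key) == "III"
    with pytest.raises(ValueError):
        load_cramer_lookup({key: "IV"})(key)


def test_tally_conservation_over_synthetic_cases(synthetic_cases):
    result = run_cases(synthetic_cases)
    tally = category_tally(result.reports)
    assert sum(tally.values()) == sum(r.matchset.n_discrete for r in result.reports)
    planted: dict[str, int] = {}
    for case in synthetic_cases:
        for cat in case.true_categories.values():
            planted[cat] = planted.get(cat, 0) + 1
    assert {k: v for k, v in tally.items() if v} == planted
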