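# pyrocast

Pyrolysis-risk forecasting for e-liquid flavour chemicals.

Vaping devices heat flavour chemicals to temperatures at which they can
decompose into new, potentially hazardous compounds before being inhaled.
`pyrocast` is a desk-scale pipeline for anticipating those risks for a
whole flavour catalogue at once:

1. **Reaction enumeration** — each flavour (as SMILES) is converted to an
   explicit-hydrogen molecular graph and candidate unimolecular pyrolysis
   transformations are enumerated as *bond-edit sets*: up to 5
   simultaneous bond-order changes over at most 16 bond-breaking
   positions, filtered so every product obeys chemical valence rules and
   element counts are conserved. Candidates are ranked by a pluggable
   scorer (the shipped baseline uses mean bond enthalpies; a learned
   reaction-ranking model can be swapped in) and the top 25 kept.
2. **EI-MS fragment matching** — both pyrolysis and electron-impact
   fragmentation are energy-driven bond-breaking processes, so predicted
   products are corroborated against each flavour's experimental EI-MS
   spectrum. A product with monoisotopic mass *M* is keyed by
   round(*M* − 1) and matches when that key equals a fragment peak m/z
   surviving a 5 % relative-abundance threshold. Products sharing the
   flavour's own nominal mass are excluded (they are the molecular ion,
   not decomposition evidence).
3. **Hazard profiling** — matched products are classified by GHS
   pictogram severity precedence (acute toxic > health hazard > irritant
   > other > not found), inhalation-relevant H-statements (H330, H331,
   H335, H340, H341, H350, H373) are extracted, Cramer classes attached,
   and everything is collated into per-flavour risk reports plus
   aggregate statistics (matches per flavour, rank histograms, category
   tallies, a product→flavours provenance index).

Supporting modules cover six-descriptor chemical-space PCA (MW, nHBDon,
nHBAcc, TopoPSA, nRotB, ALogP), acetate-ester elimination pathway
templates (acid + alkene / ketene + alcohol / two carbonyls) with an
activation-energy estimator interface and its RMSE metric, and a
synthetic-data generator that plants known products in simulated spectra
so the whole pipeline is testable offline with exact expected answers.

## Worked example

2,3-Pentanedione (`CCC(=O)C(=O)C`), a common buttery flavour, against
the packaged transcription of its printed EI-MS peak table:

```python
from pyrocast import (parse_molecule, enumerate_candidate_reactions,
                      score_and_rank, apply_threshold, match_flavour)
from pyrocast.ms_spectra import load_fixture_spectrum

flavour = parse_molecule("CCC(=O)C(=O)C")
candidates = enumerate_candidate_reactions(flavour)   # defaults: <=5 edits, 16 break sites
predictions = score_and_rank(flavour, candidates, top_k=25)

spectrum = apply_threshold(load_fixture_spectrum("pentanedione"), t=5.0)
matches = match_flavour(flavour, "2,3-pentanedione", predictions, spectrum)
for rec in matches.records:
    print(f"{rec.product.canonical_smiles:>6s}  key {rec.product_mass_key}"
          f"  -> peak m/z {rec.matched_mz}  (NN rank {rec.nn_rank})")
```

prints

```
     C  key 15  -> peak m/z 15  (NN rank 5)
     C  key 15  -> peak m/z 15  (NN rank 6)
    CC  key 29  -> peak m/z 29  (NN rank 7)
  CC=O  key 43  -> peak m/z 43  (NN rank 12)
```

Of 40 enumerated candidates, three discrete products — methane, ethane
and acetaldehyde — have mass keys (15, 29, 43) that coincide with
above-threshold fragment peaks of the flavour, flagging them as the
pyrolysis products best corroborated by experiment; acetaldehyde would
then carry its GHS/Cramer classification into the flavour's risk report.

## Command line

```bash
pyrocast simulate -n 20 --seed 1 -o data/        # synthetic flavours + spectra + lookups
pyrocast report data/flavours.smi data/spectra \
    --ghs data/ghs_lookup.json --cramer data/cramer_lookup.json -o out/
pyrocast recount --predictions out/predictions.csv --matches out/matches.csv
```

`predict`, `match` and `classify` expose the individual stages;
`recount` recomputes headline statistics (total/discrete product counts,
matches per flavour, rank shares, category tallies) from prediction,
match and classification tables in CSV or XLSX form.

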