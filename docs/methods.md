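# Methods

## The model

A pyrolysis event is modelled as an *edit set*: a set of 1–5 simultaneous
bond-order changes on the explicit-hydrogen, kekulized molecular graph of
a single reactant. Hydrogen migration is an ordinary edit (a C–H order
decrease plus an O–H or C–H order increase elsewhere), never an implicit
bookkeeping step — this keeps element conservation checkable on every
candidate. A candidate transformation is admitted only if every atom ends
at exactly the total bond order it had in the reactant, i.e. products are
valence-complete and radical-free by default. A configuration flag admits
mono-/di-radical product sets for users interested in homolysis first
steps, but it is off by default because the matching and hazard stages
are defined over closed-shell products.

A consequence worth knowing: with radical-free products, no edit set of
three or fewer changes exists at all. Breaking bonds frees valence only
on the broken pair, and the only single completing edit on that pair is
the inverse of the break; real closed-shell chemistry (eliminations,
retro-ene, enolization, dehydrogenation) starts at four edits — two
breaks and two forms. The default budget of five edits covers these plus
one further rearrangement step.

### Enumeration

1. Bonds are grouped into symmetry classes (canonical atom ranks); up to
   `max_break_sites` (default 16) classes are considered for cleavage,
   weakest mean bond enthalpy first. All member bonds of a selected class
   remain available so multi-bond edits within one class (two C–H breaks
   for an H2 elimination) are reachable.
2. Every combination of order *decreases* over those bonds is applied,
   then freed valences are completed by order *increases* between free
   atoms via a recursive matching search (pivot on the lowest-index free
   atom, partners strictly increasing, one edit per atom pair), within
   the total edit budget.
3. Product multisets are deduplicated; for each multiset the edit set
   with the best baseline score (ties: fewer edits) is kept. The identity
   outcome is discarded.

Equivalence with an independent brute force over all bond-order
reassignments (same valence rule) is asserted in the test suite for
small molecules at edit budgets 2 and 4.

### Scoring

Ranking is a `ReactionScorer` interface so a trained reaction-ranking
model can be plugged in. The shipped baseline scores an edit set as
−(Σ enthalpy of bonds broken − Σ formed) using a shipped table of ~24
mean homolytic bond enthalpies (kJ/mol, keyed `El-El:order`; unknown
pairs fall back to per-order defaults of 300/550/800 with a logged
warning). Equal scores tie-break on the lexicographic canonical product
SMILES, making `score_and_rank` a permutation-stable total order. The
top `top_k` (default 25) candidates become the flavour's predictions.

## Fragment matching

EI-MS fragment peaks are unit-mass; spectra are ingested from JCAMP-DX
peak tables (`##PEAK TABLE=(XY..XY)` / `##XYDATA`), m/z rounded to
nominal mass, abundances normalized to base peak = 100 %. A relative
abundance threshold (default 5 %, *inclusive* — the convention is
documented because printed peak lists survive either way) removes noise
and isotope satellites; matching refuses unthresholded spectra outright.

A predicted product is keyed by `round(exact_mass − offset)` with
offset 1.0 Da (an even-electron EI fragment is one hydrogen short of the
neutral product) and matches when the key equals a retained peak m/z.
Rounding is half-away-from-zero, centralized in one helper so a single
constant controls every nominal-mass decision. Products whose rounded
exact mass equals the flavour's are excluded *before* matching (the
parent-mass comparison uses rounded masses, not the −1 keys, since the
exclusion refers to the molecular ion itself). Matches are recorded per
(product, rank) and deduplicated; "discrete" statistics count each
product once per flavour. Rank histograms are computed both per record
and per discrete product (best rank), since per-rank plots can be drawn
either way.

Unit-mass matching cannot distinguish structural isomers at the same
nominal mass; that ambiguity is inherent to the method, not a bug.

## Hazard aggregation

GHS classification uses pictogram keywords mapped to three severity
buckets, with precedence acute toxic > health hazard > irritant; records
with only other warnings fall in category (iv), compounds absent from
the lookup in (v). Assignment is total and order-independent, and per-
report category counts always sum to the number of discrete matched
products (asserted on every run). Inhalation-relevant H-statements
(default {H330, H331, H335, H340, H341, H350, H373}) are extracted as
the intersection with the record's codes, order preserved. GHS and
Cramer sources are local JSON tables keyed by InChIKey; a live database
adapter can implement the same callable interface but no network access
is required or used anywhere. Lookup failures are logged per compound
and degrade to "not found" rather than aborting a report.

## Chemical-space PCA

The descriptor vector is fixed-order (MW, nHBDon, nHBAcc, TopoPSA,
nRotB, ALogP); ALogP is the Crippen atom-contribution scheme. Columns
are z-standardized by default because the units are incommensurate; the
flag is exposed because the unscaled analysis is dominated by molecular
weight. Zero-variance columns are dropped with a warning; an all-
constant matrix is a degenerate-input error. Component signs are pinned
(largest-|loading| entry positive) so projections are invariant to row
order. Variance ratios sum to 1 and are non-increasing; coordinates are
exported on the three leading components. How strongly the top three
components dominate depends on the ALogP variant and descriptor
implementation, so the top-3 share is reported, not asserted.

## Activation energies

`AEEstimator` is an interface (reactant, products) → (AE kcal/mol, sd).
The shipped baseline is Σ(bond enthalpies broken) − Σ(formed), floored
at 0 — reaction enthalpy, not a barrier. It is deliberately labelled
non-quantitative: additive mean-bond-enthalpy arithmetic carries no
transition-state information, so it cannot reproduce the kinetic
preference of acetate esters for the concerted six-centre acid + alkene
elimination; on ethyl acetate it scores the nearly thermoneutral
two-carbonyl C–O cleavage lowest. Pathway comparisons with the baseline
are therefore structural scaffolding (determinism, tie reporting,
not-applicable handling, failure isolation) until a trained estimator is
plugged in. The acetate templates themselves are explicit: pathway A
needs an sp3 alkoxy carbon with a β-hydrogen, pathway B is always
available for an acetate, pathway C needs a hydrogen on the alkoxy
carbon; all products are formula-conserving by construction. The RMSE
metric and a generic 10-fold 85/5/10 train/validation/test harness are
provided for estimator evaluation and exercised on synthetic estimators.

## Synthetic data: what it emulates and what it does not

The generator samples flavour-like molecules from a fragment grammar
(acyl, alkoxy, alkyl, aryl pieces) with functional-class proportions of
37 % esters, 26 % ketones/aldehydes, 15 % alcohols/acetals, 14 %
aromatics/heterocycles, 8 % acids/amides, molecular weight clipped to
80–250 Da (realized mean ≈ 150 Da) — the composition of a volatile
flavour catalogue. Simulated spectra contain the mass keys of *planted*
true products at 10–100 % relative abundance (the strongest pinned to
100 so normalization is exact), the molecular ion, and a floor of decoy
peaks below 5 %.

Two generator rules make end-to-end recovery a provable property rather
than chemistry luck:

* decoy peaks are resampled until their masses collide with no
  enumerable candidate's mass key;
* planted products are drawn from the ranked top-k and restricted to
  products whose mass key is unique within the ranked candidate set
  (and distinct from the parent nominal mass).

Under these conditions the pipeline must return exactly the planted
products (precision = recall = 1), and hazard tallies must equal the
planted category multinomial (drawn 11/13/19/49/8 % over the five
buckets). Passing these tests demonstrates the correctness of the
matching and aggregation machinery; it does *not* demonstrate that real
EI fragmentation corroborates real pyrolysis chemistry — real spectra
contain isomer collisions, rearrangement fragments and isotope
structure that the simulator deliberately omits.

## Problem sizes and numerical choices

Sweep-style checks run at an edit budget of 4 (the smallest budget with
real chemistry, see above): 500 molecules for formula conservation
(~50 000 candidates), 200 seeded cases for planted recovery, 180
molecules for the PCA. The default budget of 5 is exercised on
individual molecules. Enumeration cost is roughly 0.4 s per mid-size
molecule at budget 4 and ~1 s at budget 5, so catalogue-scale runs at
full depth remain practical. All randomness flows through explicit
seeds; identical configurations produce byte-identical outputs (pinned
orderings throughout).

## Known limitations

* Only first-phase unimolecular chemistry: no secondary pyrolysis of
  products, no bimolecular or combustion chemistry.
* The baseline scorer and AE estimator are enthalpy proxies; rankings
  are placeholders for learned models behind the same interfaces.
* Unit-mass matching cannot separate isomers; high-resolution masses,
  isotope patterns and MS/MS are out of scope.
* Hazard output aggregates existing GHS/Cramer classifications; it is
  not exposure or dose modelling and carries no regulatory meaning.
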