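# Methods

## Problem setting

OMOP-CDM databases drop direct identifiers during ETL, but institutional raw
codes survive in `*_source_value` columns. Combinations of these source
values can single out a patient: a combination that occurs once in the
database identifies its record outright. `cdmdeid` treats the source-value
columns (plus a handful of other risky fields: addresses, geocodes, provider
registry numbers, free-text fields) as quasi-identifiers, transforms them,
enforces a privacy model over the resulting equivalence classes, and reports
prosecutor-model re-identification risk before and after.

## Field classification and transformation

Every column of the 17 covered clinical/health-system/economics tables
resolves to one rule `(classification, action)`:

* the curated rule set (bundled as `data/cdm_v531.yaml`) covers every
  source-value field plus addresses, geocodes, provider name/NPI/DEA and the
  free-text fields; actions are **remove** (erase the whole value — the
  person source key, latitude/longitude), **mask** (suffix replacement with
  `*`), **partial_remove** (street line erased, zip keeps a 3-character
  region prefix — the Safe-Harbor-style choice), and **nlp_redact**
  (whole-value erasure of free text; a pluggable hook accepts a real
  clinical NLP de-identifier);
* unlisted fields default conservatively: any other `*_source_value` is
  masked, concept ids and surrogate keys are kept as insensitive, numeric
  clinical values and dates are kept as sensitive. No rule is guessed for
  birth dates beyond this default; deployments can override any rule in the
  run configuration.

The removal token is the empty string (unambiguous in CSV round trips); the
masking token is `*`. Masking defaults keep 5 leading characters for long
identifiers and 1 for short codes — the only calibrated reference point is
the 10-character key masked to `12345*****`, and a value no longer than its
prefix is masked entirely so short codes are never disclosed in full.

## Generalization hierarchies and the lattice

Each maskable quasi-identifier gets a suffix-masking hierarchy: level *i*
keeps the first `max(len(v) − i, 0)` characters and appends *i* fill
characters. Appending exactly *i* fill characters (rather than padding to
the original length) makes generalization a monotone coarsening and lets the
top level collapse every value to a single suppression token; the standalone
`mask_value` operator remains length-preserving. The transformation space is
the full cross-product lattice of per-field levels (full-domain global
recoding; local recoding is out of scope). Lattices at this scale are small,
so the search enumerates every node exhaustively — no pruning heuristics to
validate.

A node is **feasible** when, after discarding equivalence classes that
violate the configured model, the discarded fraction stays within
`suppression_limit` (default 1.0, since near-total elimination of risk is
preferred to infeasibility; set it lower to protect utility). **Information
loss** is the mean relative generalization level over the quasi-identifiers
plus the suppressed fraction, weighted 1:1, with ties broken toward the
lexicographically smallest level vector — a simple, reproducible surrogate
for a utility-aware score, chosen deliberately over re-implementing any
particular tool's scoring function. The search is deterministic.

## Privacy models

Classes are formed on the exact tuple of transformed quasi-identifier
values; nulls form their own category and count as a distinct sensitive
value (conservative: absent data can neither merge classes nor inflate
diversity silently).

* **k-anonymity** — every class ≥ k records (default k = 3, the minimum
  criterion in common national guidance); per-record risk ≤ 1/k.
* **l-diversity** — distinct variant: ≥ l distinct sensitive values per
  class (default l = 5). Distinct-l was chosen because it is the verbal
  definition of the model as used here; entropy-l and recursive-(c,l) are
  extension points, not defaults.
* **t-closeness** — earth-mover's distance between each class's sensitive
  distribution and the global distribution over retained records ≤ t
  (default t = 0.1). Categorical ground distance (uniform, i.e.
  total-variation) for coded values; ordered ground (normalized 1-D EMD over
  the sorted domain) for numeric sensitive fields. Suppressing a class
  shifts the global distribution, so enforcement iterates
  suppress-and-recheck to a fixed point.

Suppression removes whole rows ("discarding" a class), never individual
cells. For l/t models the sensitive field per table is configurable; by
default the first schema-ordered sensitive column (e.g. `quantity` in
DRUG_EXPOSURE) is used.

## Risk reporting

Prosecutor model: the attacker knows the target is present, so a class of
size *s* carries risk 1/s per record. Reported per table, before and after:

* **records at risk** — % of records with risk strictly above the threshold
  τ (default 0.2; strict comparison makes τ = 1/k report exactly zero after
  k-anonymity enforcement — the threshold itself is configurable because no
  canonical value exists);
* **highest risk** — 100 / (smallest class size);
* **success rate** — mean risk = 100 · n_classes / n_records; equal to the
  marketer-model success rate under the full-population assumption. The
  journalist model needs a population sampling frame and is out of scope.

Rendering rounds to two decimals; positive values below the printable
resolution render as `<0.01`.

Tables whose `rows × cols` exceed 2³² − 1 are uniformly row-sampled down to
that cell budget before analysis, reproducibly from the run seed.

## Synthetic data

The generator emits CDM-shaped tables (exact v5.3.1 column lists) whose
source-value columns hold short alphanumeric codes (3–8 characters, so
hierarchies have non-trivial depth) drawn from configurable-cardinality
domains with Zipf-skewed frequencies (default exponent 1.2, cardinality 8 —
head-heavy marginals resembling coded clinical vocabularies). Event tables
link to PERSON by uniform `person_id` foreign keys, with Poisson row counts
per person (mean 3).

Controllable re-identifiability comes from **planted classes**: exact
equivalence-class sizes planted on reserved codes disjoint from the coded
domains (`planted_unique` plants that many singletons), with background
classes floored at a configurable minimum size so the rare combinations are
exactly the planted ones. This makes class-size-dependent outcomes (risk
ceilings of 1/3, 1/4, the 100% unique-record ceiling) deterministic for any
seed.

What the generator does **not** emulate: real vocabularies and code
semantics, longitudinal/clinical coherence between tables, realistic
missingness, and cross-field correlation among quasi-identifiers. Passing
tests therefore demonstrate the correctness of the partitioning, models,
search and reporting machinery — not that any particular real database is
safe at k = 3, which depends on its actual source-value joint distribution.

## Numerical and degenerate-input choices

* Distribution inputs must sum to 1 within 1e-9; model comparisons use a
  1e-12 slack so boundary cases (distance exactly t, fraction exactly at the
  limit) count as satisfied.
* Empty tables short-circuit: empty result, zeroed report flagged with
  n = 0. An empty quasi-identifier list puts every row in one class.
* An empty hierarchy value set is an error; a constant column yields a
  1-level hierarchy.
* All randomness (sampling, generation) flows from explicit integer seeds;
  identical inputs and seed give byte-identical outputs.

## Problem sizes

Tests and the acceptance script run on synthetic tables of 60–5000 persons
(most at 100–200) with quasi-identifier domains of 1–10 codes. These sizes
put every construction deep inside exhaustive-lattice territory while still
exercising multi-table runs; the machinery itself is vectorized over pandas
and handles larger exports, with the cell-budget sampler guarding the
extreme end.

## Known limitations

* Full-domain global recoding only; no local recoding or cell suppression.
* Free-text handling is whole-value redaction unless a redactor is plugged
  in; token-level de-identification is explicitly out of scope.
* No population-uniqueness estimators, δ-presence or differential privacy.
* The information-loss surrogate ignores value semantics (all fields weigh
  equally); utility analysis beyond suppression/generalization accounting is
  out of scope.
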