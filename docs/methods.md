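# Methods

## The metadata model

The package implements a five-level hierarchy: Investigation → Study →
Observation unit → Sample → Assay. The two inner levels extend the
classic three-level ISA framework; they exist because
minimal-information checklists centre on the sampling environment, and
field scientists find "source material"/"sample material" confusingly
similar. The model keeps the alignment explicit: the observation-unit
class is declared `owl:equivalentClass` to classic ISA source material
and the sample class to sample material, as class-level links in every
exported graph (instance-level `sameAs` is deliberately not emitted).

Each level's records are flat attribute→string maps. Hierarchy linkage
is by explicit parent-identifier columns
(`investigation_identifier` … `sample_identifier`), the only
machine-checkable linkage in a multi-sheet workbook. Identifiers must
match `[A-Za-z0-9][A-Za-z0-9_.-]*` (compared case-sensitively) so they
are safe for IRI minting and ENA aliases. Referential-integrity
violations are *reported, never raised*: a broken workbook still parses
so that one validation pass can list every problem. Duplicate
identifiers keep their first occurrence for graph building.

One workbook is one investigation. Cells may hold multiple values
separated by `;` only for attributes flagged `multivalued` in the
library (contact columns, data-file names); otherwise the raw string is
a single value.

## The checklist library

The bundled library contains 40 packages — 23 MIxS (6 base checklists
and 17 environmental packages) and 17 ENA-style checklists (15 sample
checklists and 2 sequencing-assay packages) — plus per-level core
attributes included regardless of the chosen package. The exact
membership and attribute sets of the original 40-checklist catalogue
are not published, so this set is a curated, representative stand-in
transcribed once at a pinned version (`2026.1`); tests depend only on
the counts and a small set of named attributes. The published
sample-volume pattern is retained verbatim, including its unescaped
dots (`(0.)` matches `0` followed by *any* character): fidelity to the
source checklist is preferred over silent correction, and the tests
document the consequence.

Patterns are evaluated as fully anchored (implicit `^…$`, via
`re.fullmatch`) in Python's standard engine; the library linter rejects
patterns that fail to compile. The requirement vocabulary is
mandatory/optional only — no "recommended" tier.

## Validation semantics

All applicable rules fire for every cell (no short-circuit); a single
pass yields the complete report, sorted (sheet, row, attribute) for
determinism. Severities: format violations and identifier mismatches
are errors; auto-correction suspicion and unknown headers are warnings,
because user-defined columns are a legitimate, first-class feature.
Values are stripped of surrounding whitespace before validation
(silently — the issue vocabulary is kept closed rather than adding a
whitespace rule). Dates are ISO 8601 (`YYYY-MM-DD`, optional time),
with a real calendar check on top of the pattern.

Ontology-term matching is exact on trimmed, case-folded `rdfs:label`
values — no fuzzy matching and no synonym properties. Ontology
documents (RDF/XML or Turtle) load from local files or from a
content-addressed on-disk cache; `offline=True` turns a cache miss into
an error instead of a retrieval, so validation never touches the
network unexpectedly.

Auto-correction detection uses the native spreadsheet cell type
recorded at parse time: a date-typed cell under a non-date attribute, a
numeric cell whose display diverges from its stored value under a text
attribute, or a bare number in the Excel serial-date range under a date
attribute. Generated templates format all data columns as text to make
such conversions less likely in the first place.

The JSON Schema export (draft-07) mirrors exactly the requirement +
pattern rule subset: mandatory attributes get `minLength: 1` and are
listed in `required`; optional patterns are wrapped to admit the empty
string; multivalued patterns are repeated around `;`. Verdict
equivalence with an independent JSON Schema engine is property-tested
on ≥10⁴ randomized cases. Two caveats are inherent: ontology
membership and the calendar check on dates (e.g. `2026-02-30`) are not
expressible as a pattern, so the schema is an over-approximation there.

## RDF export and querying

Entity IRIs are minted deterministically as
`<base>/<level>/<urlencoded-identifier>` (default base
`http://fairbydesign.nl/data`). Vocabulary bindings live in one
editable table: people FOAF, investigation/study/sample/assay classes
JERM, observation unit PPEO, derivation `prov:wasDerivedFrom`
(sample→unit, assay→sample), containment `schema:isPartOf`
(study→investigation, unit→study), titles/descriptions/identifiers
Schema.org, checklist attributes under a MIxS-rooted namespace, and
user-defined columns slugified (lowercase, non-alphanumerics → `_`)
into a project-local namespace. Literals are plain strings except
booleans and plain dates, which carry XSD datatypes when the library
declares the kind. The original tool's exact predicate IRIs are not
published; this mapping is the package's own documented choice.

No RDF library is available in the target environment, so the graph is
a native triple set with its own Turtle writer (sorted, prefixed,
deterministic) and reader. The reader covers the subset the writer
emits plus what simple OWL ontologies need (prefixed names, IRIs,
escaped string literals, datatypes, language tags, `a`, `;`/`,`
continuation, numeric/boolean shorthand); blank nodes and collections
are out of scope. Likewise `run_sparql` is a restricted engine —
`PREFIX`, `SELECT`/`ASK`, `DISTINCT`, a single `COUNT` aggregate, basic
graph patterns and simple equality `FILTER` — intended for desk-scale
queries; real triple stores remain the target for anything larger. The
dual route (direct triple scan in `find_samples_where` vs the pattern
engine) is kept deliberately and cross-checked in tests.

## ENA conversion

One STUDY per study, one SAMPLE per sample, one EXPERIMENT per assay,
one RUN per assay with data files (paired FASTQ files become two FILE
blocks in one RUN). Observation-unit attributes are folded into each
descendant SAMPLE (sample value wins on collision, with a warning);
empty values are omitted. Each SAMPLE carries an `ENA-CHECKLIST`
attribute with the configured accession (default ERC000011). Aliases
are `<investigation>_<record>`, collision-checked. Submission actions
are `ADD` only, plus an optional `HOLD` with date; output is
deterministic (stable ordering, no timestamps).

Because neither an XML Schema engine nor the SRA XSD files are
available offline, `validate_submission` checks a distilled structural
rule set (`src/fairds/data/sra_rules.json`, a hand-written synthetic
stand-in): required elements and attributes, the SRA controlled
vocabularies for platform/library descriptors and file types, checksum
syntax, and the experiment→sample/study and run→experiment reference
graph. It covers the constraints this package can produce or violate;
it is not a complete XSD validation.

## Synthetic fixtures

The generator emulates a small freshwater monitoring campaign (the
`mixs_water` checklist plus a short-read assay package): defaults of 1
study × 2 stations × 2 replicate samples × 1 assay, conforming values
drawn from a seeded RNG, a 12-term ENVO-like toy ontology, and tiny
FASTQ files so checksummed RUN blocks can be built. Same seed ⇒
byte-identical outputs (workbook timestamps are pinned). Error
injection perturbs distinct sample rows, one error per injection, and
writes a manifest of the exact expected issues — the oracle for the
validator's end-to-end test.

What the fixtures do *not* emulate: hand-edited workbooks (merged
cells, formulas, locale-formatted numbers), large projects, real
ontology scale, or the long tail of real ENA checklist attributes. A
green test establishes that the pipeline is correct on well-formed,
desk-scale input; it says nothing about robustness to arbitrarily
mangled spreadsheets.

## Known limitations

* The 40-checklist catalogue is representative, not a byte-level copy
  of any published library.
* SPARQL and Turtle support are restricted subsets (documented above).
* ENA validation is structural, not XSD-complete, and nothing is ever
  uploaded; classic ISA-Tab serialization is not produced.
* Ontology validation is label-only; no reasoning or synonym expansion.
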