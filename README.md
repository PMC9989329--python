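# fairds

Checklist-driven metadata management for omics studies: generate
minimal-information metadata template workbooks, validate recorded
sample metadata, export it as an RDF knowledge graph in Turtle, and
convert it into ENA-compatible XML submission files.

## Who this is for

Data producers and data managers in (meta)genomics and microbiome
research who need their experiment metadata to be machine-actionable
from day one: complete per an accepted minimal-information standard,
syntactically valid, queryable across projects, and ready for sequence
archive submission — without a server, a database, or a network
connection. Spreadsheets stay the registration medium because that is
what works in the field and at the bench; everything around the
spreadsheet is automated and checked.

## The model

Metadata is organised in an extended five-level ISA hierarchy

```
Investigation ─ Study ─ Observation unit ─ Sample ─ Assay
```

where the two levels inserted between Study and Assay separate the
entity under study (*observation unit*, equivalent to classic ISA
"source material") from the biological material taken from it
(*sample*, equivalent to "sample material"). Many samples can be taken
per observation unit and many assays run per sample.

What a sample record must contain is defined by a **package**: a
minimal-information checklist with mandatory and optional attributes,
each carrying a syntax rule. The bundled library holds 40 checklists —
23 MIxS standards (MIGS/MIMS/MIMARKS/MISAG/MIMAG plus the environmental
packages) and 17 checklists in the style of the ENA sample checklist
portal — on top of a core attribute set that applies at every level
regardless of the chosen package. Restricted values are validated with
anchored regular expressions in the ENA checklist convention, for
example the sample-volume rule

```
(0|((0.)|([1-9][0-9]*.?))[0-9]*)([Ee][+-]?[0-9]+)? (g|mL|mg|ng)
```

under which `3.5 mg` is valid and `3.5 kg` is not. Boolean attributes
accept exactly `true`/`false`; dates are ISO 8601; ontology-term
attributes are checked against the `rdfs:label` vocabulary of the
configured OWL document (e.g. the Environment Ontology).

Validated projects export to RDF: one typed node per record
(FOAF/JERM/PPEO/PROV/Schema.org/MIxS vocabularies), one triple per
attribute, `owl:equivalentClass` links tying the inserted levels to the
classic ISA material classes, and user-defined workbook columns minted
as predicates in a project-local namespace. Merged graphs from several
projects answer cross-project questions ("all samples where attribute X
is true") directly or via SPARQL.

## Worked example

`examples/02_validate_workbook.py` generates the demo project with two
errors injected and validates it:

```
is_valid: False
counts:   {'error': 2, 'warning': 0}
sheet                row  severity  rule            attribute
Sample - mixs_water    2  error     bad_boolean     oxygenic: 'yes' is not a boolean; use exactly 'true' or 'false'
Sample - mixs_water    3  error     unknown_parent  observation_unit_identifier: sample 'SA2' references unknown observation_unit 'OU_missing'
```

Every issue is addressed to a sheet, row and attribute so the data
producer can fix the exact cell. `examples/03_rdf_export_and_query.py`
continues the pipeline: the clean 4-sample demo project yields an RDF
graph of 137 triples, `find_samples_where(graph, "oxygenic", "true")`
returns the identifiers of the oxygenated samples, and merging two
project graphs (270 triples) makes the same query span both projects.
`examples/04_ena_submission.py` converts the project into 1 STUDY, 4
SAMPLE, 4 EXPERIMENT and 4 RUN records with MD5-checksummed file blocks
and zero structural violations. The other examples cover template
generation and JSON Schema export for ELIXIR-Biovalidator-style
validation.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch — library build and load,
seeded fixture generation, workbook parsing, full validation, RDF
export with a Turtle round trip and a SPARQL count, and ENA submission
construction with structural validation — logging each stage to stderr
and writing the JSON result object to `--out`. A non-zero exit means a
stage failed.
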