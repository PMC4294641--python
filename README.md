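# ontoetl

Ontology-driven ETL for structured-but-uncoded clinical data.

Electronic medical records hold large amounts of structured data that is
not linked to any standard terminology: assessment forms with locally
defined elements and value lists, often stored generically in
entity-attribute-value (EAV) tables. Reusing that data for research
normally means hand-writing and hand-maintaining one SQL extraction job
per data element — thousands of them, all opaque and unreusable.

`ontoetl` replaces those hand-written jobs with **declarative knowledge in
RDF ontologies**, from which executable SQL is generated:

* a **source ontology** inventories the source system's data elements and
  records their database bindings (table, columns, EAV select filter),
* a **target ontology** describes the research dataset's concepts with the
  metadata an i2b2-like platform needs (hierarchical path, code, datatype,
  unit),
* a **mapping ontology** connects the two: simple `hasImport` links for
  one-to-one copies, and cascadable *mapping nodes* — each with a command
  type and exactly two ordered operands — for arbitrary transformations.

The compiler schedules the mapping nodes (a node runs once both operands'
data are available), emits one SQL statement per node from a single
template, and loads the results into a minimal i2b2-like star schema
(concept metadata + observation facts, with per-node provenance).

All operand and result data travels in a six-column **internal data
model**: `DocumentID, PatientID, CaseID, DateStartValue, DateEndValue,
Value`. Operand record sets are joined on the document, so computations
relate data entered on the same form instance.

An **in-memory reference evaluator** implements the same algebra over
plain records and serves as the executable specification: the test suite
checks that executing the generated SQL and evaluating in memory produce
identical record sets on randomized synthetic EMR databases.

## The mapping algebra in brief

A mapping expression in bracketed prefix notation, e.g.

```
Gleason3: IF (NOTEXISTS Gleason3 Gleason1) (ADD Gleason1 Gleason2)
```

reads: *if no total Gleason score was documented, export the sum of the
two pattern grades as the total score*. Command types include `ADD`,
`EQUALS`, `GREATER`, `GREATERVT`, `EXISTS`, `NOTEXISTS`, `IF`, tolerant
arithmetic variants and string concatenation. Strict commands drop a row
when an operand is missing; tolerant ones substitute the neutral element
(0 or 1 for arithmetic, `""` for strings). *Column overloading*
(`Gleason1 hasDateStartValueColumn DateBiops`) replaces an internal-model
column with another element's value from the same document — e.g. the
biopsy date instead of the form's storage date.

## Worked example

The package ships a self-contained fixture of the classic compound-score
case: a prostate pathology form documents the two Gleason pattern grades
(2 and 3) and the biopsy date (2011-03-04) as separate EAV rows, all
stamped with the form's storage date (2011-05-06).

```
$ ontoetl demo
patient  concept   value  start_date  provenance
12345  GLEASON3  5      2011-03-04  Gleason3_IF_1
```

One fact is exported: the total score **5** (= 2 + 3, computed by the
`ADD` node because no total was documented), dated **2011-03-04** — the
overloaded biopsy date, not the storage date — with the producing mapping
node recorded as provenance.

Other subcommands: `ontoetl compile` (ontologies → deterministic `.sql`
script), `ontoetl run` (compile + execute + load, YAML config),
`ontoetl validate`, `ontoetl stats` (node-type counts and redundancy
report), `ontoetl build-source-ontology` (EAV metadata CSV → source
ontology).

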