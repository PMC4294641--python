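# Methods

## Model

The package treats an ETL process as three declarative artifacts plus a
compiler. An *ontology* here is simply a directed graph of RDF triples;
the class/instance distinction is collapsed (every concept is a plain
resource), which changes nothing about the semantics of binding
resolution, mapping evaluation or SQL generation. Canonical serialization
is Turtle (human-readable diffs); RDF/XML is accepted for input. The
vocabulary namespace is fixed (`https://ontoetl.dev/vocab#`, prefix
`oe`); unknown predicates in foreign namespaces are preserved untouched,
unknown predicates *inside* the tool namespace are flagged by the
validator as likely typos.

### Source bindings

A source concept denotes a record set: all rows of one data element,
projected to the six-column internal data model `(DocumentID, PatientID,
CaseID, DateStartValue, DateEndValue, Value)`. The six-column form is the
executable model throughout; the didactic three-column form `(PatientID,
Value, Date)` is just a projection of it. Binding knowledge (table
resource, column names, access-SQL template) may sit on the concept, on
any `rdfs:subClassOf` ancestor, or on the table resource — nearest
definition wins. This matters at scale: EAV systems bind tens of
thousands of elements to one table, and inheritance lets the table be
declared once on the form or root concept. Per-concept `hasSelectFilter`
fragments (e.g. `Attribute = 'GL1'`) distinguish elements within the
shared table.

All values travel as *text*. EAV value columns are untyped, and text
transport keeps the SQL and in-memory paths identical; dates are ISO-8601
strings, so lexicographic order coincides with temporal order. The SQL
generator explicitly casts every node's value expression to text so that
arithmetic results remain comparable by downstream relational nodes.

Filter and transformation fragments from the ontologies are spliced into
the generated SQL **verbatim** (after OP1/OP2 placeholder substitution).
That is deliberate: the fragments are the ontology author's chosen
dialect, and splicing is what makes the template mechanism general. The
consequence — ontology authors are trusted like SQL authors — is a
documented property of the approach, not an accident.

### Column overloading

`ConceptA hasXColumn ConceptB` with a *resource* object (X one of
DocumentID, PatientID, CaseID, DateStartValue, DateEndValue) replaces
column X of A's records with the Value of B's record from the same
document. Compiled as a correlated sub-select with `COALESCE` fallback:

* a document without a supplier record keeps its default column value
  (form storage dates are usually an acceptable default, so absence must
  not destroy the record);
* a document with several supplier records uses the lexicographically
  smallest value (`MIN`), making the result deterministic.

### Mapping nodes

Every intermediate node has a command type and exactly two **ordered**
operands (`hasOperand1`/`hasOperand2`), enabling non-commutative
operations; operands are source concepts, constants, or other nodes.
Constants are modeled as operand resources carrying a literal
(`hasConstantValue`), keeping the two-operand node shape uniform; at
evaluation a constant expands to a virtual record per document of the
real operand. A node with two constant operands is rejected — it would
anchor to no records.

Join semantics per command category:

| command | join on document | filter | value | dates from |
|---|---|---|---|---|
| ADD, MULTIPLY | inner | both operands present | numeric op | OP1 |
| ADD_TOLERANT, MULTIPLY_TOLERANT | full outer | — | numeric op, neutral 0 / 1 | OP1 (fallback OP2) |
| CONCAT | full outer | — | concatenation, neutral "" | OP1 (fallback OP2) |
| EQUALS, EXISTS | inner | OP1 = OP2 | 'TRUE' | OP1 |
| GREATER | inner | OP1 > OP2 | 'TRUE' | OP1 |
| GREATERVT | OP2-driven left | OP1 absent **or** OP1 > OP2 | 'TRUE' | OP2 |
| NOTEXISTS | OP2-driven left | OP1 absent | 'TRUE' | OP2 |
| IF | inner | OP1 = 'TRUE' | OP2's value | OP2 |

Decisions worth recording:

* **NOTEXISTS** needs operand 2 because operand 2 supplies the entities:
  the node emits one `TRUE` record per operand-2 document lacking an
  operand-1 record. With operand 1 entirely absent, every operand-2
  document qualifies.
* **GREATERVT** ("operand 1 can be NULL") passes when operand 1 is
  absent. Its use case is temporal first/last-value selection, where a
  missing competing value must not block the selection.
* **Comparison typing.** `GREATER`/`GREATERVT` compare numerically when
  both values are numeric text (digits with at most one dot), else
  lexicographically — EAV values are untyped, and `"10" > "9"` should
  hold for scores. `EQUALS`/`EXISTS` use exact text equality on both
  paths, matching SQL VARCHAR equality; treating `"2.0"` and `"2"` as
  equal in memory but unequal in SQL would break the oracle guarantee.
  Values that look numeric but do not parse (e.g. `"1.2.3"`) have
  backend-dependent ordering; the fixture generators never emit them.
* **Join key.** Records join on `DocumentID`; records without a document
  fall back to a composite `patient|date_start` key (identically in SQL
  and in memory), so synthetic edge cases have defined behavior.
* **Result identity columns** coalesce operand 1 before operand 2 (only
  observable on outer joins); result timestamps come from the operand
  named by the command's `hasDateValue`, falling back to the other side
  when that operand is absent or undated.
* **Duplicates.** All operand pairs within a document join, then the
  result is deduplicated (`SELECT DISTINCT` / set semantics in memory).

### Scheduling and compilation

A node is ready once both operands' data exist; source concepts are
always ready. The scheduler is a Kahn topological sort with ready nodes
ordered by id — deterministic where a random valid order would also be
correct (order independence is itself tested), because reproducible
byte-identical ETL scripts are worth more than scheduling freedom.
Cycles are reported with the participating node ids.

Each node compiles to `DROP TABLE IF EXISTS` + `CREATE TABLE … AS SELECT
DISTINCT …` on a deterministic temp table (`etl_tmp_` + sanitized node
id); each statement also emits a `NodeName` provenance column. Simple
imports compile to pass-through statements. Final loads `DELETE` the
mapping's previous facts by provenance before `INSERT`, so re-running a
script is idempotent. The star schema is a deliberately minimal i2b2-like
pair — `concept_dimension` (code, backslash-separated hierarchical path,
name, datatype, unit, description) and `observation_fact` (document,
patient, case, concept code, dates, value, provenance) — not a real i2b2
installation.

The dialect hook (`EmbeddedDialect`/`AnsiDialect`) concentrates literal
quoting, join keywords and the numeric-aware comparison. The embedded
dialect targets SQLite (which is also the execution engine for tests and
the demo); the ANSI variant drops SQLite-only constructs and is the
extension point for production backends. Mapping expressions are parsed
by a small recursive-descent parser (grammar: `Target ":" Expr`,
`Expr := "(" CMD Arg Arg ")" | name | quoted`); the root command may
appear without enclosing brackets, as mapping editors print it. Command
names are case-insensitive on input, canonical uppercase in triples.

Hierarchical-level mappings (operands that have narrower concepts, e.g. a
whole form) are rejected with an explicit error rather than silently
expanded.

## Synthetic data

The generators emulate the *shape* of generic EMR storage, not clinical
content:

* **Gleason fixture** — one patient (12345), one document, EAV rows
  `Gleason1=2`, `Gleason2=3`, `DateBiops=2011-03-04`, storage date
  2011-05-06; the conditional mapping above plus a simple import of the
  documented total. Expected export: value 5 dated 2011-03-04 (or the
  documented total when present). A column-oriented variant of the same
  data must evaluate identically.
* **Random EMR** (`FixtureSpec`) — defaults: 20 patients, 3 forms, 4
  elements/form, element missingness 0.2, document probability 0.9, both
  storage layouts. Elements alternate numeric value sets (integers 1–6,
  keeping arithmetic total and sum formatting exact) and string code sets
  (A–E). Identifiers are zero-padded decimals, dates ISO-8601 in
  2010–2015. Same spec + seed ⇒ identical database and ontology.
* **Random mappings** (`MappingSpec`) — trees of depth ≤ 4 over the full
  command registry, mixing strict/tolerant nodes and constants; operand
  typing is respected (arithmetic sees only numeric elements/constants)
  so evaluation is total.

What the fixtures do **not** model: realistic clinical value
distributions, intra-document repeated measurements with meaningful
semantics, NULL values inside stored EAV rows, multi-table EAV systems,
or concurrent writes. Passing the oracle-equivalence property therefore
shows that the compiler and evaluator agree on the algebra over
EAV/column data of this shape — it does not validate any clinical
mapping's medical correctness, which remains the mapping author's
judgment.

## Test design and problem sizes

The central property is **oracle equivalence**: on 100 seeded random
fixtures (5–50 patients, 2–10 forms, missingness up to 0.6, both
layouts, mapping trees of depth ≤ 4), executing the generated SQL equals
the in-memory evaluation exactly, as sets over all six columns. Further
properties: 200-DAG schedule validity with brute-force dependency
checking, exhaustive 4-combination missing-value semantics per
strict/tolerant operator, 100 serialization round-trips, and
byte-determinism of compiled scripts. These sizes keep the whole suite
within a few seconds while covering the combinatorics the algebra
actually has (join kind × operand presence × constant placement ×
layout).

## Known limitations

* Only the SQLite-backed embedded dialect is executable in-package; the
  ANSI dialect emits plain lexicographic comparison unless overridden.
* Command types declared in user ontologies compile to SQL but have no
  in-memory semantics unless registered in Python; the evaluator refuses
  them rather than guessing.
* The evaluator is quadratic per join and intended for fixture-sized
  data only.
* Connection resources store a name/URL for resolution by the caller;
  credential management is out of scope.
* No OWL reasoning, remote triple stores, or automated schema matching.
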