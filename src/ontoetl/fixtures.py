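"""Self-contained synthetic EMR fixtures.

Everything in this package is testable without external data: this module
builds small SQLite databases in the two storage layouts real EMR systems
use (entity-attribute-value rows, and one column per data element), plus
the matching source ontologies, target ontologies and mapping networks.

Two generators matter:

* :func:`make_gleason_fixture` — the canonical worked example: a prostate
  pathology form documenting the two Gleason pattern grades (values 2 and
  3), whose sum is the total Gleason score (5), with the biopsy date
  (2011-03-04) stored in a sibling field while the form itself carries
  only its storage date (2011-05-06).
* :func:`make_random_emr` / :func:`make_random_mapping` — seeded random
  databases and mapping trees, the substrate for the oracle-equivalence
  property: generated SQL must agree with the in-memory evaluator on
  every fixture.

Identifiers are zero-padded decimal strings and dates ISO-8601 within
2010–2015, so lexicographic order coincides with temporal/numeric order
where the algebra relies on it.  Same spec + seed → identical database
content and ontologies.
"""
from __future__ import annotations

import datetime
import random
import sqlite3
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdflib import Literal, URIRef
from rdflib.namespace import RDFS

from . import vocab
from .errors import OntoETLError
from .mapping_algebra import (
    Constant,
    ConceptRef,
    MappingGraph,
    MappingNode,
    NameResolver,
    NodeRef,
    builtin_command_registry,
    parse_mapping_file,
)
from .ontology_store import OntologyGraph
from .reference_evaluator import Record, RecordSet
from .source_binding import generate_source_ontology

GLEASON_BASE = "https://ontoetl.dev/fixtures/gleason/"
RANDOM_BASE = "https://ontoetl.dev/fixtures/random/"


# ---------------------------------------------------------------------------
# Gleason worked example
# ---------------------------------------------------------------------------

#: raw EAV rows: (DocID, PatID, CaseID, Attribute, Value, SaveDate)
GLEASON_EAV_ROWS = (
    ("doc1", "12345", None, "GL1", "2", "2011-05-06"),
    ("doc1", "12345", None, "GL2", "3", "2011-05-06"),
    ("doc1", "12345", None, "DATB", "2011-03-04", "2011-05-06"),
)

GLEASON_MAPPING_TEXT = (
    "# export the documented total score when present, else the sum\n"
    "Gleason3: Gleason3\n"
    "Gleason3: IF (NOTEXISTS Gleason3 Gleason1) (ADD Gleason1 Gleason2)\n"
)


@dataclass
class GleasonFixture:
    connection: sqlite3.Connection
    source_ontology: OntologyGraph
    target_ontology: OntologyGraph
    mapping: MappingGraph
    #: brute-force record sets per source concept (pre-overloading)
    source_data: dict
    raw_rows: tuple
    layout: str
    source_iris: dict
    target_iri: str


def _gleason_source_ontology(layout: str) -> tuple:
    base = GLEASON_BASE + "source#"
    g = OntologyGraph()
    form = URIRef(base + "ProstateForm")
    table = URIRef(base + "MyEMRTable")
    conn = URIRef(base + "MyDBConnection")
    g.add((form, RDFS.label, Literal("Prostate pathology form")))
    g.add((form, vocab.HAS_SOURCE_TABLE, table))
    g.add((table, vocab.HAS_DB_CONNECTION, conn))
    g.add((conn, vocab.HAS_CONNECTION_URL, Literal("sqlite://:memory:")))
    elements = {}
    if layout == "eav":
        g.add((table, vocab.HAS_SOURCE_TABLE_NAME, Literal("MyEMRData")))
        g.add((table, vocab.HAS_DOCUMENT_ID_COLUMN, Literal("DocID")))
        g.add((table, vocab.HAS_PATIENT_ID_COLUMN, Literal("PatID")))
        g.add((table, vocab.HAS_VALUE_COLUMN, Literal("Value")))
        g.add((table, vocab.HAS_DATE_COLUMN, Literal("SaveDate")))
        for name, code in (("Gleason1", "GL1"), ("Gleason2", "GL2"),
                           ("Gleason3", "GL3"), ("DateBiops", "DATB")):
            el = URIRef(base + name)
            elements[name] = el
            g.add((el, RDFS.label, Literal(name)))
            g.add((el, RDFS.subClassOf, form))
            g.add((el, vocab.HAS_SELECT_FILTER, Literal(f"Attribute = '{code}'")))
    elif layout == "column":
        g.add((table, vocab.HAS_SOURCE_TABLE_NAME, Literal("MyEMRWide")))
        g.add((table, vocab.HAS_DOCUMENT_ID_COLUMN, Literal("DocID")))
        g.add((table, vocab.HAS_PATIENT_ID_COLUMN, Literal("PatID")))
        g.add((table, vocab.HAS_DATE_COLUMN, Literal("SaveDate")))
        for name in ("Gleason1", "Gleason2", "Gleason3", "DateBiops"):
            el = URIRef(base + name)
            elements[name] = el
            g.add((el, RDFS.label, Literal(name)))
            g.add((el, RDFS.subClassOf, form))
            g.add((el, vocab.HAS_VALUE_COLUMN, Literal(name)))
            g.add((el, vocab.HAS_SELECT_FILTER, Literal(f"{name} IS NOT NULL")))
    else:
        raise OntoETLError(f"unknown layout {layout!r}")
    # the biopsy date, not the storage date, is the clinically correct
    # timestamp of both pattern grades
    g.add((elements["Gleason1"], vocab.HAS_DATE_START_VALUE_COLUMN, elements["DateBiops"]))
    g.add((elements["Gleason2"], vocab.HAS_DATE_START_VALUE_COLUMN, elements["DateBiops"]))
    return g, elements


def _gleason_target_ontology() -> tuple:
    base = GLEASON_BASE + "target#"
    g = OntologyGraph()
    root = URIRef(base + "Prostate")
    g.add((root, RDFS.label, Literal("Prostate")))
    leaf = URIRef(base + "Gleason3")
    g.add((leaf, RDFS.label, Literal("Gleason Score 3")))
    g.add((leaf, RDFS.subClassOf, root))
    g.add((leaf, vocab.HAS_CONCEPT_CODE, Literal("GLEASON3")))
    g.add((leaf, vocab.HAS_DATA_TYPE, Literal("numeric")))
    return g, leaf


def make_gleason_fixture(
    include_gleason3: Optional[str] = None,
    layout: str = "eav",
    connection: Optional[sqlite3.Connection] = None,
) -> GleasonFixture:
    """Database + ontologies + mapping for the Gleason worked example.

    ``include_gleason3`` adds a documented total score to the source data,
    exercising the NOTEXISTS branch of the conditional mapping: when the
    total is present it is exported as-is; when absent, the sum of the two
    pattern grades is exported instead.
    """
    rows = list(GLEASON_EAV_ROWS)
    if include_gleason3 is not None:
        rows.append(("doc1", "12345", None, "GL3", include_gleason3, "2011-05-06"))
    conn = connection or sqlite3.connect(":memory:")
    cur = conn.cursor()
    if layout == "eav":
        cur.execute("DROP TABLE IF EXISTS MyEMRData")
        cur.execute(
            "CREATE TABLE MyEMRData (DocID TEXT, PatID TEXT, CaseID TEXT, "
            "Attribute TEXT, Value TEXT, SaveDate TEXT)"
        )
        cur.executemany("INSERT INTO MyEMRData VALUES (?, ?, ?, ?, ?, ?)", rows)
    elif layout == "column":
        cur.execute("DROP TABLE IF EXISTS MyEMRWide")
        cur.execute(
            "CREATE TABLE MyEMRWide (DocID TEXT, PatID TEXT, CaseID TEXT, "
            "Gleason1 TEXT, Gleason2 TEXT, Gleason3 TEXT, DateBiops TEXT, "
            "SaveDate TEXT)"
        )
        by_attr = {r[3]: r[4] for r in rows}
        cur.execute(
            "INSERT INTO MyEMRWide VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            ("doc1", "12345", None, by_attr.get("GL1"), by_attr.get("GL2"),
             by_attr.get("GL3"), by_attr.get("DATB"), "2011-05-06"),
        )
    else:
        raise OntoETLError(f"unknown layout {layout!r}")
    conn.commit()

    source, elements = _gleason_source_ontology(layout)
    target, target_leaf = _gleason_target_ontology()
    resolver = NameResolver(source, target)
    mapping = parse_mapping_file(GLEASON_MAPPING_TEXT, resolver)

    attr_of = {"Gleason1": "GL1", "Gleason2": "GL2", "Gleason3": "GL3",
               "DateBiops": "DATB"}
    source_data = {}
    for name, el in elements.items():
        recs = [
            Record(document_id=r[0], patient_id=r[1], case_id=r[2],
                   date_start=r[5], date_end=None, value=r[4])
            for r in rows
            if r[3] == attr_of[name]
        ]
        source_data[str(el)] = RecordSet(str(el), recs).deduplicated()

    return GleasonFixture(
        connection=conn,
        source_ontology=source,
        target_ontology=target,
        mapping=mapping,
        source_data=source_data,
        raw_rows=tuple(rows),
        layout=layout,
        source_iris={k: str(v) for k, v in elements.items()},
        target_iri=str(target_leaf),
    )


# ---------------------------------------------------------------------------
# Random EMR fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Shape parameters of a synthetic EMR database."""

    n_patients: int = 20
    n_forms: int = 3
    elements_per_form: int = 4
    missingness: float = 0.2
    seed: int = 0
    layout: str = "eav"  # "eav" | "column"
    #: probability that a patient has a document for a given form
    p_document: float = 0.9
    value_sets: Optional[Sequence[Sequence[str]]] = None

    def __post_init__(self):
        for p, name in ((self.missingness, "missingness"), (self.p_document, "p_document")):
            if not 0.0 <= p <= 1.0:
                raise OntoETLError(f"{name} must be a probability, got {p}")
        if self.layout not in ("eav", "column"):
            raise OntoETLError(f"unknown layout {self.layout!r}")


@dataclass
class ElementMeta:
    iri: str
    element_id: str
    form_id: str
    kind: str  # "numeric" | "string"
    values: tuple


@dataclass
class RandomEMR:
    connection: sqlite3.Connection
    source_ontology: OntologyGraph
    elements: list
    #: brute-force record sets per element IRI — the extraction oracle
    source_data: dict
    raw_rows: list
    spec: FixtureSpec


def _random_date(rng: random.Random) -> str:
    start = datetime.date(2010, 1, 1)
    return (start + datetime.timedelta(days=rng.randrange(0, 6 * 365))).isoformat()


def make_random_emr(spec: FixtureSpec,
                    connection: Optional[sqlite3.Connection] = None) -> RandomEMR:
    """Seeded synthetic EMR database with controlled missingness.

    Elements alternate between numeric value sets (small integers, so
    arithmetic nodes stay well-defined) and string code sets.  The EAV
    layout stores one row per documented element; the column-oriented
    layout one row per document with NULL for missing elements.  Both are
    generated from the same logical data, so their record sets agree.
    """
    rng = random.Random(spec.seed)
    base = RANDOM_BASE + f"s{spec.seed}#"

    elements: list[ElementMeta] = []
    metadata_rows = []
    for f in range(1, spec.n_forms + 1):
        form_id = f"F{f:02d}"
        for e in range(1, spec.elements_per_form + 1):
            element_id = f"{form_id}E{e:02d}"
            idx = len(elements)
            if spec.value_sets:
                values = tuple(spec.value_sets[idx % len(spec.value_sets)])
                kind = "numeric" if all(v.isdigit() for v in values) else "string"
            elif idx % 2 == 0:
                values = tuple(str(v) for v in range(1, 7))
                kind = "numeric"
            else:
                values = tuple(string.ascii_uppercase[:5])
                kind = "string"
            elements.append(ElementMeta(base + element_id, element_id, form_id,
                                        kind, values))
            for v in values:
                metadata_rows.append(
                    (form_id, f"Form {f}", element_id, f"Element {element_id}",
                     v, f"Value {v}", f"Attribute = '{element_id}'")
                )

    # logical documents: (doc_id, patient_id, case_id, save_date, form_id,
    #                     {element_id: value})
    documents = []
    doc_counter = 0
    for p in range(1, spec.n_patients + 1):
        patient = f"P{p:04d}"
        for f in range(1, spec.n_forms + 1):
            if rng.random() >= spec.p_document:
                continue
            doc_counter += 1
            doc = f"D{doc_counter:06d}"
            case = f"C{p:04d}"
            save_date = _random_date(rng)
            form_id = f"F{f:02d}"
            entries = {}
            for el in elements:
                if el.form_id != form_id:
                    continue
                if rng.random() < spec.missingness:
                    continue
                entries[el.element_id] = rng.choice(el.values)
            documents.append((doc, patient, case, save_date, form_id, entries))

    conn = connection or sqlite3.connect(":memory:")
    cur = conn.cursor()
    raw_rows = []
    if spec.layout == "eav":
        source = generate_source_ontology(
            metadata_rows, base_iri=base, table_name="EMRDATA",
            document_id_column="DocID", patient_id_column="PatID",
            case_id_column="CaseID", value_column="Value", date_column="SaveDate",
        )
        cur.execute("DROP TABLE IF EXISTS EMRDATA")
        cur.execute(
            "CREATE TABLE EMRDATA (DocID TEXT, PatID TEXT, CaseID TEXT, "
            "Attribute TEXT, Value TEXT, SaveDate TEXT)"
        )
        for doc, patient, case, save_date, _form_id, entries in documents:
            for element_id in sorted(entries):
                raw_rows.append((doc, patient, case, element_id,
                                 entries[element_id], save_date))
        cur.executemany("INSERT INTO EMRDATA VALUES (?, ?, ?, ?, ?, ?)", raw_rows)
    else:
        # one wide table per form, elements as columns
        source = OntologyGraph()
        for f in range(1, spec.n_forms + 1):
            form_id = f"F{f:02d}"
            form = URIRef(base + form_id)
            table = URIRef(base + "Table_" + form_id)
            source.add((form, RDFS.label, Literal(f"Form {f}")))
            source.add((form, vocab.HAS_SOURCE_TABLE, table))
            source.add((table, vocab.HAS_SOURCE_TABLE_NAME, Literal(f"EMR_{form_id}")))
            source.add((table, vocab.HAS_DOCUMENT_ID_COLUMN, Literal("DocID")))
            source.add((table, vocab.HAS_PATIENT_ID_COLUMN, Literal("PatID")))
            source.add((table, vocab.HAS_CASE_ID_COLUMN, Literal("CaseID")))
            source.add((table, vocab.HAS_DATE_COLUMN, Literal("SaveDate")))
            form_elements = [el for el in elements if el.form_id == form_id]
            for el in form_elements:
                node = URIRef(el.iri)
                source.add((node, RDFS.label, Literal(f"Element {el.element_id}")))
                source.add((node, RDFS.subClassOf, form))
                source.add((node, vocab.HAS_VALUE_COLUMN, Literal(el.element_id)))
                source.add((node, vocab.HAS_SELECT_FILTER,
                            Literal(f"{el.element_id} IS NOT NULL")))
            cols = ", ".join(f"{el.element_id} TEXT" for el in form_elements)
            cur.execute(f"DROP TABLE IF EXISTS EMR_{form_id}")
            cur.execute(
                f"CREATE TABLE EMR_{form_id} (DocID TEXT, PatID TEXT, "
                f"CaseID TEXT, SaveDate TEXT, {cols})"
            )
            for doc, patient, case, save_date, doc_form, entries in documents:
                if doc_form != form_id:
                    continue
                if not entries:
                    continue  # fully missing documents carry no rows in either layout
                vals = [entries.get(el.element_id) for el in form_elements]
                placeholders = ", ".join("?" for _ in range(4 + len(form_elements)))
                cur.execute(
                    f"INSERT INTO EMR_{form_id} VALUES ({placeholders})",
                    (doc, patient, case, save_date, *vals),
                )
                for element_id in sorted(entries):
                    raw_rows.append((doc, patient, case, element_id,
                                     entries[element_id], save_date))
    conn.commit()

    source_data = {}
    for el in elements:
        recs = [
            Record(document_id=doc, patient_id=patient, case_id=case,
                   date_start=save_date, date_end=None, value=value)
            for (doc, patient, case, attr, value, save_date) in raw_rows
            if attr == el.element_id
        ]
        source_data[el.iri] = RecordSet(el.iri, recs).deduplicated()

    return RandomEMR(conn, source, elements, source_data, raw_rows, spec)


# ---------------------------------------------------------------------------
# Random mapping networks
# ---------------------------------------------------------------------------

@dataclass
class MappingSpec:
    n_targets: int = 3
    n_simple: int = 2
    max_depth: int = 3
    p_constant: float = 0.2
    seed: int = 0
    commands: Optional[Sequence[str]] = None


ARITHMETIC = ("ADD", "ADD_TOLERANT", "MULTIPLY", "MULTIPLY_TOLERANT")
BOOLEAN_OUT = ("EQUALS", "GREATER", "GREATERVT", "EXISTS", "NOTEXISTS")


def make_random_mapping(emr: RandomEMR, spec: MappingSpec) -> tuple:
    """Random well-formed mapping trees over a fixture's elements.

    Returns ``(mapping_graph, target_ontology)``.  Trees respect operand
    typing: arithmetic nodes only ever see numeric-valued elements or
    numeric constants, so evaluation is total on the fixture data.
    Every generated graph passes :meth:`MappingGraph.validate`.
    """
    rng = random.Random(spec.seed)
    registry = builtin_command_registry()
    allowed = [c for c in (spec.commands or list(registry)) if c in registry]
    numeric_elements = [el for el in emr.elements if el.kind == "numeric"]
    string_elements = [el for el in emr.elements if el.kind == "string"]
    if not numeric_elements or not string_elements:
        raise OntoETLError("fixture needs both numeric and string elements")

    base = RANDOM_BASE + f"target-s{spec.seed}#"
    target_graph = OntologyGraph()
    root = URIRef(base + "Dataset")
    target_graph.add((root, RDFS.label, Literal("Research dataset")))

    nodes: list[MappingNode] = []
    counter = [0]

    def new_id(target_name: str, cmd: str) -> str:
        counter[0] += 1
        return f"{target_name}_{cmd}_{counter[0]}"

    def leaf(kind: str):
        if kind == "numeric":
            if rng.random() < spec.p_constant:
                return Constant(str(rng.randrange(0, 9))), "numeric"
            return ConceptRef(rng.choice(numeric_elements).iri), "numeric"
        pool = emr.elements
        if rng.random() < spec.p_constant:
            el = rng.choice(pool)
            return Constant(rng.choice(el.values)), el.kind
        el = rng.choice(pool)
        return ConceptRef(el.iri), el.kind

    def subtree(target_name: str, depth: int):
        """Returns (operand, kind) where kind is 'numeric'|'string'|'bool'."""
        if depth <= 0 or rng.random() < 0.35:
            return leaf("numeric" if rng.random() < 0.5 else "any")
        cmd = rng.choice(allowed)
        if cmd in ARITHMETIC:
            op1, _ = subtree_typed(target_name, depth - 1, "numeric")
            op2, _ = subtree_typed(target_name, depth - 1, "numeric")
            kind = "numeric"
        elif cmd in BOOLEAN_OUT:
            op1, _ = subtree(target_name, depth - 1)
            op2, _ = subtree(target_name, depth - 1)
            kind = "bool"
        elif cmd == "CONCAT":
            op1, _ = subtree(target_name, depth - 1)
            op2, _ = subtree(target_name, depth - 1)
            kind = "string"
        else:  # IF
            op1, _ = subtree_typed(target_name, depth - 1, "bool")
            op2, k2 = subtree(target_name, depth - 1)
            kind = k2
        # constants on both sides would make the node sourceless
        if isinstance(op1, Constant) and isinstance(op2, Constant):
            op2 = ConceptRef(rng.choice(numeric_elements).iri)
        nid = new_id(target_name, cmd)
        nodes.append(MappingNode(nid, cmd, op1, op2))
        return NodeRef(nid), kind

    def subtree_typed(target_name: str, depth: int, want: str):
        if want == "numeric":
            if depth <= 0 or rng.random() < 0.4:
                return leaf("numeric")
            cmd = rng.choice([c for c in ARITHMETIC if c in allowed] or ["ADD"])
            op1, _ = subtree_typed(target_name, depth - 1, "numeric")
            op2, _ = subtree_typed(target_name, depth - 1, "numeric")
            if isinstance(op1, Constant) and isinstance(op2, Constant):
                op2 = ConceptRef(rng.choice(numeric_elements).iri)
            nid = new_id(target_name, cmd)
            nodes.append(MappingNode(nid, cmd, op1, op2))
            return NodeRef(nid), "numeric"
        if want == "bool":
            cmd = rng.choice([c for c in BOOLEAN_OUT if c in allowed] or ["EXISTS"])
            op1, _ = subtree(target_name, max(depth - 1, 0))
            op2, _ = subtree(target_name, max(depth - 1, 0))
            if isinstance(op1, Constant) and isinstance(op2, Constant):
                op2 = ConceptRef(rng.choice(emr.elements).iri)
            nid = new_id(target_name, cmd)
            nodes.append(MappingNode(nid, cmd, op1, op2))
            return NodeRef(nid), "bool"
        raise AssertionError(want)

    graph = MappingGraph()
    for i in range(1, spec.n_simple + 1):
        t = URIRef(base + f"S{i:02d}")
        target_graph.add((t, RDFS.label, Literal(f"Simple target {i}")))
        target_graph.add((t, RDFS.subClassOf, root))
        el = rng.choice(emr.elements)
        graph.simple_mappings.append((str(t), el.iri))
    for i in range(1, spec.n_targets + 1):
        name = f"T{i:02d}"
        t = URIRef(base + name)
        target_graph.add((t, RDFS.label, Literal(f"Complex target {i}")))
        target_graph.add((t, RDFS.subClassOf, root))
        op, _ = subtree(name, spec.max_depth)
        if isinstance(op, NodeRef):
            idx = next(j for j, n in enumerate(nodes) if n.id == op.node_id)
            nodes[idx] = MappingNode(nodes[idx].id, nodes[idx].command,
                                     nodes[idx].operand1, nodes[idx].operand2,
                                     output_concept=str(t))
        else:
            # tree collapsed to a leaf: make it a simple mapping instead
            src = op.iri if isinstance(op, ConceptRef) else rng.choice(emr.elements).iri
            graph.simple_mappings.append((str(t), src))
    graph.nodes = nodes
    graph.validate(registry)
    return graph, target_graph
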