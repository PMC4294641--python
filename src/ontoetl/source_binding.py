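"""Resolve database bindings of source concepts and build operand-fetch SQL.

A source concept abstracts a *record set*: all rows in the source database
that belong to one data element, projected into the six-column internal
data model (DocumentID, PatientID, CaseID, DateStartValue, DateEndValue,
Value).  The binding knowledge — which table, which columns, which EAV
select filter — lives entirely in the source ontology; this module turns
it into a single ``SELECT DISTINCT``.

Column *overloading* replaces one internal-data-model column of a concept
with the Value of another concept's record from the same document (the
classic case: a form's storage date replaced by the biopsy date documented
in a sibling field).  It compiles to a correlated sub-select with a
fallback to the default column when the supplying concept has no record
for the document.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS

from . import vocab
from .errors import BindingError, GenerationError, OntoETLError
from .ontology_store import OntologyGraph

#: Default operand-fetch template (``hasAccessSQL`` overrides it per table).
#: Placeholders are filled with column names, ``NULL`` for unmapped columns,
#: or correlated sub-selects for overloaded columns.
DEFAULT_ACCESS_SQL = (
    "SELECT DISTINCT {document_id} AS DocumentID, {patient_id} AS PatientID, "
    "{case_id} AS CaseID, {date_start} AS DateStartValue, "
    "{date_end} AS DateEndValue, {value} AS Value FROM {table}{where}"
)

#: internal-model column -> TableBinding attribute holding its default source
_COLUMN_ATTRS = {
    "document_id": "document_id_column",
    "patient_id": "patient_id_column",
    "case_id": "case_id_column",
    "date_start": "date_start_column",
    "date_end": "date_end_column",
}


@dataclass
class TableBinding:
    """Resolved database access description for one source concept."""

    concept: str
    source_table_name: str
    connection_ref: Optional[str] = None
    patient_id_column: str = ""
    value_column: str = ""
    date_column: str = ""
    document_id_column: Optional[str] = None
    case_id_column: Optional[str] = None
    date_start_column: Optional[str] = None
    date_end_column: Optional[str] = None
    select_filter: str = ""
    access_sql_template: str = DEFAULT_ACCESS_SQL

    def __post_init__(self):
        # hasDateColumn is the didactic single-date form; it feeds
        # DateStartValue unless an explicit start column is given.
        if not self.date_start_column and self.date_column:
            self.date_start_column = self.date_column
        if not self.patient_id_column:
            raise BindingError(f"{self.concept}: no patient ID column mapped")
        if not self.value_column:
            raise BindingError(f"{self.concept}: no value column mapped")


@dataclass(frozen=True)
class ColumnOverload:
    """``owner hasXColumn supplier`` with a *resource* object: column overload."""

    owner_concept: str
    overloaded_column: str  # internal-model attribute name, e.g. "date_start"
    supplier_concept: str


def resolve_binding(graph: OntologyGraph, concept: URIRef) -> TableBinding:
    """Assemble the full binding of ``concept`` from the source ontology.

    Column properties may sit on the concept itself (as literals), on any
    ``rdfs:subClassOf`` ancestor, or on the bound table resource; the
    nearest definition wins, so a form can share one table declaration
    among thousands of elements.
    """
    table = graph.inherited_value(concept, vocab.HAS_SOURCE_TABLE)
    if table is None:
        raise BindingError(
            f"source concept {concept} has no hasSourceTable on itself or any ancestor"
        )
    table_name = graph.literal(table, vocab.HAS_SOURCE_TABLE_NAME)
    if not table_name:
        raise BindingError(f"table resource {table} has no hasSourceTableName")

    def col(predicate) -> Optional[str]:
        # concept (and ancestors) first, then the table resource; only
        # literal objects name columns — resource objects are overloads.
        for node in graph.ancestors(concept) + [table]:
            lit = graph.literal(node, predicate)
            if lit is not None:
                return lit
        return None

    connection = graph.value(table, vocab.HAS_DB_CONNECTION)
    template = graph.literal(table, vocab.HAS_ACCESS_SQL) or DEFAULT_ACCESS_SQL
    return TableBinding(
        concept=str(concept),
        source_table_name=table_name,
        connection_ref=str(connection) if connection is not None else None,
        patient_id_column=col(vocab.HAS_PATIENT_ID_COLUMN) or "",
        value_column=col(vocab.HAS_VALUE_COLUMN) or "",
        date_column=col(vocab.HAS_DATE_COLUMN) or "",
        document_id_column=col(vocab.HAS_DOCUMENT_ID_COLUMN),
        case_id_column=col(vocab.HAS_CASE_ID_COLUMN),
        date_start_column=col(vocab.HAS_DATE_START_VALUE_COLUMN),
        date_end_column=col(vocab.HAS_DATE_END_VALUE_COLUMN),
        select_filter=graph.literal(concept, vocab.HAS_SELECT_FILTER) or "",
        access_sql_template=template,
    )


def resolve_overloads(graph: OntologyGraph, concept: URIRef) -> list:
    """Column overloads declared on ``concept`` (resource-valued hasXColumn)."""
    out = []
    for predicate, column in vocab.OVERLOADABLE_COLUMNS.items():
        for _, _, obj in graph.query_pattern(concept, predicate, None):
            if isinstance(obj, URIRef):
                out.append(ColumnOverload(str(concept), column, str(obj)))
    return sorted(out, key=lambda o: (o.overloaded_column, o.supplier_concept))


def build_fetch_sql(
    binding: TableBinding,
    overloads: Sequence[ColumnOverload] = (),
    overload_bindings: Optional[Mapping[str, TableBinding]] = None,
    dialect=None,
) -> str:
    """The operand-fetch ``SELECT`` for one source concept.

    Returns a single statement producing the six internal-data-model
    columns.  Unmapped columns are emitted as ``NULL``.  Each overloaded
    column becomes a correlated sub-select taking the lexicographically
    smallest Value of the supplier's records in the same document, with
    ``COALESCE`` fallback to the default column.
    """
    from .sql_generator import EmbeddedDialect  # local import: avoid cycle

    dialect = dialect or EmbeddedDialect()
    overload_bindings = overload_bindings or {}
    by_column = {}
    for ov in overloads:
        by_column.setdefault(ov.overloaded_column, ov)

    def column_expr(internal: str) -> str:
        default_col = getattr(binding, _COLUMN_ATTRS[internal])
        default_expr = default_col if default_col else "NULL"
        ov = by_column.get(internal)
        if ov is None:
            return default_expr
        try:
            sup = overload_bindings[ov.supplier_concept]
        except KeyError:
            raise GenerationError(
                f"overload of {internal} on {binding.concept}: supplier "
                f"{ov.supplier_concept} has no resolved binding"
            ) from None
        if not sup.document_id_column or not binding.document_id_column:
            raise GenerationError(
                f"overload of {internal} on {binding.concept}: both concepts "
                "need a DocumentID column to join on"
            )
        where = f" AND ov.{sup.select_filter}" if sup.select_filter else ""
        sub = (
            f"(SELECT MIN(ov.{sup.value_column}) FROM {sup.source_table_name} ov "
            f"WHERE ov.{sup.document_id_column} = "
            f"{binding.source_table_name}.{binding.document_id_column}{where})"
        )
        return f"COALESCE({sub}, {default_expr})"

    where = f" WHERE {binding.select_filter}" if binding.select_filter else ""
    fields = {
        "document_id": column_expr("document_id"),
        "patient_id": column_expr("patient_id"),
        "case_id": column_expr("case_id"),
        "date_start": column_expr("date_start"),
        "date_end": column_expr("date_end"),
        "value": binding.value_column,
        "table": binding.source_table_name,
        "where": where,
        "filter": binding.select_filter,
    }
    try:
        return binding.access_sql_template.format(**fields)
    except (KeyError, IndexError) as exc:
        raise GenerationError(
            f"access SQL template of {binding.concept} has an unresolved "
            f"placeholder: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# Source ontology generation from EAV metadata
# ---------------------------------------------------------------------------

#: Column order of the delimited metadata input.
METADATA_COLUMNS = (
    "form_id", "form_label", "element_id", "element_label",
    "value_code", "value_label", "select_filter",
)


def generate_source_ontology(
    metadata_rows: Iterable[Sequence[str]],
    base_iri: str = "https://ontoetl.dev/source#",
    table_name: str = "EMRDATA",
    connection_name: str = "SourceDB",
    document_id_column: str = "DocID",
    patient_id_column: str = "PatID",
    case_id_column: Optional[str] = None,
    value_column: str = "Value",
    date_column: str = "SaveDate",
) -> OntologyGraph:
    """Build a two-level source ontology (forms → elements) from EAV metadata.

    Each metadata row is ``(form id, form label, element id, element label,
    value code, value label, filter fragment)``; elements without an
    enumerated value list use empty value columns.  All elements inherit
    one table/connection binding from the ontology root, so the binding is
    declared exactly once no matter how many thousand elements exist.
    """
    rows = [tuple(r) for r in metadata_rows]
    if not rows:
        raise OntoETLError("metadata is empty; at least one row required")
    for r in rows:
        if len(r) != len(METADATA_COLUMNS):
            raise OntoETLError(
                f"metadata row has {len(r)} columns, expected {len(METADATA_COLUMNS)}: {r!r}"
            )

    g = OntologyGraph()
    base = base_iri.rstrip("#/") + "#"

    root = URIRef(base + "SourceRoot")
    table = URIRef(base + "Table_" + table_name)
    conn = URIRef(base + "Connection_" + connection_name)
    g.add((root, RDFS.label, Literal("Source system inventory")))
    g.add((root, vocab.HAS_SOURCE_TABLE, table))
    g.add((table, vocab.HAS_SOURCE_TABLE_NAME, Literal(table_name)))
    g.add((table, vocab.HAS_DB_CONNECTION, conn))
    g.add((conn, RDFS.label, Literal(connection_name)))
    g.add((table, vocab.HAS_DOCUMENT_ID_COLUMN, Literal(document_id_column)))
    g.add((table, vocab.HAS_PATIENT_ID_COLUMN, Literal(patient_id_column)))
    if case_id_column:
        g.add((table, vocab.HAS_CASE_ID_COLUMN, Literal(case_id_column)))
    g.add((table, vocab.HAS_VALUE_COLUMN, Literal(value_column)))
    g.add((table, vocab.HAS_DATE_COLUMN, Literal(date_column)))

    seen_elements: dict[tuple, tuple] = {}
    element_iris: dict[str, URIRef] = {}
    for form_id, form_label, element_id, element_label, value_code, value_label, flt in rows:
        form = URIRef(base + form_id)
        g.add((form, RDFS.label, Literal(form_label)))
        g.add((form, RDFS.subClassOf, root))
        if not element_id:
            continue
        key = (form_id, element_id)
        signature = (element_label, flt)
        if key in seen_elements and seen_elements[key] != signature:
            raise OntoETLError(
                f"duplicate element id {element_id!r} in form {form_id!r} "
                "with conflicting label/filter"
            )
        if element_id in element_iris and key not in seen_elements:
            raise OntoETLError(
                f"element id {element_id!r} reused across forms; ids must be unique"
            )
        seen_elements[key] = signature
        element = URIRef(base + element_id)
        element_iris[element_id] = element
        g.add((element, RDFS.label, Literal(element_label)))
        g.add((element, RDFS.subClassOf, form))
        if flt:
            g.add((element, vocab.HAS_SELECT_FILTER, Literal(flt)))
        if value_code:
            v = URIRef(base + element_id + "." + value_code)
            g.add((element, vocab.HAS_PERMISSIBLE_VALUE, v))
            g.add((v, vocab.HAS_VALUE_CODE, Literal(value_code)))
            if value_label:
                g.add((v, RDFS.label, Literal(value_label)))
    return g


def read_metadata_csv(text_or_path) -> list:
    """Read the seven-column metadata CSV (header optional)."""
    if hasattr(text_or_path, "read"):
        fh = text_or_path
    elif isinstance(text_or_path, str) and "\n" in text_or_path:
        fh = io.StringIO(text_or_path)
    else:
        fh = open(text_or_path, newline="", encoding="utf-8")
    with fh:
        rows = [tuple(r) for r in csv.reader(fh) if r]
    if rows and tuple(rows[0]) == METADATA_COLUMNS:
        rows = rows[1:]
    return rows
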