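"""Compile a scheduled mapping network into an executable SQL script.

One statement per mapping node, all built from a single template: two
operand sub-selects in the six-column internal data model, a join on the
entity (DocumentID), the command type's output transformation spliced as
the value expression, its select filter spliced as the WHERE clause, date
columns taken from the operand the command names, and a NodeName
provenance column.  Each statement materializes its node's output in a
temporary table consumed by downstream statements; final-load statements
move the root and simple-mapping results into the target star schema.

SQL fragments from the ontologies (select filters, output
transformations) are spliced verbatim after OP1/OP2 placeholder
substitution — the ontology author writes the dialect she targets.  A
small dialect object concentrates the remaining backend differences
(literal quoting, numeric-aware comparison, temp-table naming).
"""
from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from rdflib import URIRef

from . import vocab
from .errors import ExecutionError, GenerationError, MappingError
from .mapping_algebra import (
    JOIN_INNER,
    JOIN_OP2_LEFT,
    JOIN_OUTER,
    Constant,
    ConceptRef,
    MappingGraph,
    MappingNode,
    NodeRef,
    builtin_command_registry,
)
from .ontology_store import OntologyGraph
from .source_binding import (
    ColumnOverload,
    TableBinding,
    build_fetch_sql,
    resolve_binding,
    resolve_overloads,
)
from .vocab import local_name

INTERNAL_COLUMNS = ("DocumentID", "PatientID", "CaseID",
                    "DateStartValue", "DateEndValue", "Value")

TEMP_PREFIX = "etl_tmp_"

_SANITIZE_RE = re.compile(r"[^A-Za-z0-9_]")


def temp_table_name(node_id: str) -> str:
    return TEMP_PREFIX + _SANITIZE_RE.sub("_", node_id)


class EmbeddedDialect:
    """SQL dialect for the embedded engine (SQLite) and near-ANSI targets."""

    name = "embedded"

    def quote_literal(self, text: str) -> str:
        return "'" + text.replace("'", "''") + "'"

    def numeric_greater(self, a: str, b: str) -> str:
        """Numeric comparison when both values are numeric text, else lexicographic."""
        numeric = (
            f"{a} <> '' AND {b} <> '' AND "
            f"{a} NOT GLOB '*[^0-9.]*' AND {b} NOT GLOB '*[^0-9.]*'"
        )
        return (
            f"(CASE WHEN {numeric} THEN CAST({a} AS REAL) > CAST({b} AS REAL) "
            f"ELSE {a} > {b} END)"
        )

    def join_keyword(self, join: str) -> str:
        return {JOIN_INNER: "JOIN", JOIN_OUTER: "FULL OUTER JOIN",
                JOIN_OP2_LEFT: "LEFT JOIN"}[join]

    def drop_table(self, name: str) -> str:
        return f"DROP TABLE IF EXISTS {name}"


class AnsiDialect(EmbeddedDialect):
    """Strict-ANSI variant: no GLOB, plain (lexicographic) comparison.

    Intended as the hook for production backends, which would override
    :meth:`numeric_greater` with a vendor regex/TRANSLATE test.
    """

    name = "ansi"

    def numeric_greater(self, a: str, b: str) -> str:
        return f"({a} > {b})"


DIALECTS = {"embedded": EmbeddedDialect, "ansi": AnsiDialect}


def _join_key_expr(alias: str) -> str:
    # Records without a document join on a patient/date composite; mirrors
    # reference_evaluator.join_key exactly.
    return (
        f"COALESCE({alias}.DocumentID, 'p|' || {alias}.PatientID || '|' || "
        f"COALESCE({alias}.DateStartValue, ''))"
    )


@dataclass
class SQLStatement:
    node_id: str
    parts: list  # individual executable statements, in order
    creates_table: Optional[str] = None
    reads_tables: list = field(default_factory=list)
    comment: str = ""

    @property
    def text(self) -> str:
        head = f"-- {self.comment}\n" if self.comment else ""
        return head + ";\n".join(self.parts) + ";"


@dataclass
class ETLScript:
    statements: list = field(default_factory=list)   # node/import temp tables
    final_load: list = field(default_factory=list)   # star-schema inserts
    dialect: str = "embedded"

    @property
    def all_statements(self) -> list:
        return list(self.statements) + list(self.final_load)

    def sql_text(self) -> str:
        blocks = [s.text for s in self.all_statements]
        return "\n\n".join(blocks) + ("\n" if blocks else "")


@dataclass
class StatementReport:
    node_id: str
    rows: int
    seconds: float


@dataclass
class RunReport:
    entries: list = field(default_factory=list)

    @property
    def total_rows(self) -> int:
        return sum(e.rows for e in self.entries)

    def to_json(self) -> str:
        return json.dumps(
            {
                "statements": [
                    {"node": e.node_id, "rows": e.rows, "seconds": round(e.seconds, 6)}
                    for e in self.entries
                ],
                "total_rows": self.total_rows,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Per-node statement generation
# ---------------------------------------------------------------------------

@dataclass
class _OperandSource:
    """Where one operand's records come from in SQL terms."""

    kind: str                       # "subquery" | "constant"
    sql: Optional[str] = None       # fetch subquery or temp table select
    literal: Optional[str] = None   # constant text


def _operand_source(
    op,
    bindings: Mapping[str, TableBinding],
    overloads: Mapping[str, Sequence[ColumnOverload]],
    upstream: Mapping[str, str],
    dialect,
) -> _OperandSource:
    if isinstance(op, Constant):
        return _OperandSource("constant", literal=op.value)
    if isinstance(op, NodeRef):
        try:
            table = upstream[op.node_id]
        except KeyError:
            raise GenerationError(
                f"operand references node {op.node_id} with no upstream temp table"
            ) from None
        cols = ", ".join(INTERNAL_COLUMNS)
        return _OperandSource("subquery", sql=f"SELECT {cols} FROM {table}")
    try:
        binding = bindings[op.iri]
    except KeyError:
        raise GenerationError(f"no table binding resolved for concept {op.iri}") from None
    fetch = build_fetch_sql(binding, overloads.get(op.iri, ()), bindings, dialect)
    return _OperandSource("subquery", sql=fetch)


def generate_node_sql(
    node: MappingNode,
    registry: dict,
    bindings: Mapping[str, TableBinding],
    overloads: Mapping[str, Sequence[ColumnOverload]] = (),
    upstream: Optional[Mapping[str, str]] = None,
    dialect: Optional[EmbeddedDialect] = None,
) -> SQLStatement:
    """The temp-table statement for one mapping node."""
    dialect = dialect or EmbeddedDialect()
    upstream = upstream or {}
    overloads = overloads or {}
    try:
        cmd = registry[node.command]
    except KeyError:
        raise MappingError(f"node {node.id}: unknown command type {node.command}") from None

    s1 = _operand_source(node.operand1, bindings, overloads, upstream, dialect)
    s2 = _operand_source(node.operand2, bindings, overloads, upstream, dialect)
    if s1.kind == "constant" and s2.kind == "constant":
        raise GenerationError(f"node {node.id}: both operands are constants")

    # Value expressions of the two operands, and the alias of the single
    # real operand when the other is a constant.
    if s1.kind == "constant":
        real, const_side = "o2", 1
        op1_val = dialect.quote_literal(s1.literal)
        op2_val = "o2.Value"
    elif s2.kind == "constant":
        real, const_side = "o1", 2
        op1_val = "o1.Value"
        op2_val = dialect.quote_literal(s2.literal)
    else:
        real, const_side = None, 0
        op1_val, op2_val = "o1.Value", "o2.Value"

    # A constant operand always "exists" (it mirrors the real operand's
    # documents); an absent operand 1 is detectable by its NULL join key.
    if const_side == 1:
        op1_absent = "1 = 0"
    elif real == "o1" or cmd.join == JOIN_INNER:
        op1_absent = "1 = 0"
    else:
        op1_absent = "o1.DocumentID IS NULL AND o1.PatientID IS NULL"

    fragments = {"op1": op1_val, "op2": op2_val,
                 "op1_gt_op2": dialect.numeric_greater(op1_val, op2_val),
                 "op1_absent": op1_absent}

    def splice(template: str) -> str:
        try:
            return template.format(**fragments)
        except (KeyError, IndexError) as exc:
            raise GenerationError(
                f"node {node.id}: unresolved placeholder in command fragment: {exc}"
            ) from exc

    # values travel as text throughout the internal model; casting here keeps
    # arithmetic results comparable by downstream relational nodes
    value_expr = f"CAST(({splice(cmd.output_transformation)}) AS TEXT)"
    where = splice(cmd.select_filter) if cmd.select_filter else ""

    # Identity and date columns; COALESCE mirrors the evaluator precisely.
    if real is not None:
        ident = {c: f"{real}.{c}" for c in INTERNAL_COLUMNS[:5]}
        date_cols = (f"{real}.DateStartValue", f"{real}.DateEndValue")
        from_clause = f"FROM ({(s1 if real == 'o1' else s2).sql}\n) {real}"
    else:
        ident = {
            "DocumentID": "COALESCE(o1.DocumentID, o2.DocumentID)",
            "PatientID": "COALESCE(o1.PatientID, o2.PatientID)",
            "CaseID": "COALESCE(o1.CaseID, o2.CaseID)",
        }
        od, oo = ("o1", "o2") if cmd.date_value_source == "OP1" else ("o2", "o1")
        # the named operand's dates, falling back to the other side when it
        # is absent or undated — mirrors the evaluator's coalescing exactly
        date_cols = (
            f"COALESCE({od}.DateStartValue, {oo}.DateStartValue)",
            f"COALESCE({od}.DateEndValue, {oo}.DateEndValue)",
        )
        join_kw = dialect.join_keyword(cmd.join)
        cond = f"{_join_key_expr('o1')} = {_join_key_expr('o2')}"
        if cmd.join == JOIN_OP2_LEFT:
            from_clause = (f"FROM ({s2.sql}\n) o2\n{join_kw} ({s1.sql}\n) o1"
                           f"\n  ON {cond}")
        else:
            from_clause = (f"FROM ({s1.sql}\n) o1\n{join_kw} ({s2.sql}\n) o2"
                           f"\n  ON {cond}")

    tmp = temp_table_name(node.id)
    select = (
        "SELECT DISTINCT\n"
        f"  {ident['DocumentID']} AS DocumentID,\n"
        f"  {ident['PatientID']} AS PatientID,\n"
        f"  {ident['CaseID']} AS CaseID,\n"
        f"  {date_cols[0]} AS DateStartValue,\n"
        f"  {date_cols[1]} AS DateEndValue,\n"
        f"  {value_expr} AS Value,\n"
        f"  {dialect.quote_literal(node.id)} AS NodeName\n"
        f"{from_clause}"
    )
    if where:
        select += f"\nWHERE {where}"

    reads = []
    for s, op in ((s1, node.operand1), (s2, node.operand2)):
        if isinstance(op, NodeRef):
            reads.append(temp_table_name(op.node_id))
        elif isinstance(op, ConceptRef):
            reads.append(bindings[op.iri].source_table_name)
    return SQLStatement(
        node_id=node.id,
        parts=[dialect.drop_table(tmp), f"CREATE TABLE {tmp} AS\n{select}"],
        creates_table=tmp,
        reads_tables=sorted(set(reads)),
        comment=f"node {node.id} ({node.command})",
    )


def _import_statement(target: str, source: str, bindings, overloads, dialect) -> SQLStatement:
    """Pass-through statement for a simple hasImport mapping (no join)."""
    node_id = f"import_{local_name(target)}_{local_name(source)}"
    try:
        binding = bindings[source]
    except KeyError:
        raise GenerationError(f"no table binding resolved for concept {source}") from None
    fetch = build_fetch_sql(binding, overloads.get(source, ()), bindings, dialect)
    tmp = temp_table_name(node_id)
    select = (
        "SELECT DISTINCT "
        + ", ".join(f"s.{c}" for c in INTERNAL_COLUMNS)
        + f", {dialect.quote_literal(node_id)} AS NodeName\nFROM ({fetch}\n) s"
    )
    return SQLStatement(
        node_id=node_id,
        parts=[dialect.drop_table(tmp), f"CREATE TABLE {tmp} AS\n{select}"],
        creates_table=tmp,
        reads_tables=[binding.source_table_name],
        comment=f"simple import {local_name(source)} -> {local_name(target)}",
    )


def _final_load_statement(target: str, tmp: str, concept_code: str,
                          fact_table: str, node_id: str, dialect) -> SQLStatement:
    code = dialect.quote_literal(concept_code)
    provenance_filter = f"provenance = {dialect.quote_literal(node_id)}"
    insert = (
        f"INSERT INTO {fact_table} (document_id, patient_id, case_id, "
        f"concept_cd, start_date, end_date, value, provenance)\n"
        f"SELECT DocumentID, PatientID, CaseID, {code}, DateStartValue, "
        f"DateEndValue, Value, NodeName FROM {tmp}"
    )
    return SQLStatement(
        node_id=f"load_{node_id}",
        # delete-before-insert keeps re-runs idempotent per mapping
        parts=[f"DELETE FROM {fact_table} WHERE {provenance_filter}", insert],
        reads_tables=[tmp],
        comment=f"load {concept_code} from {tmp}",
    )


def generate_script(
    mapping: MappingGraph,
    source_graph: OntologyGraph,
    target_graph: Optional[OntologyGraph] = None,
    registry: Optional[dict] = None,
    dialect: Optional[EmbeddedDialect] = None,
    fact_table: str = "observation_fact",
) -> ETLScript:
    """Compile the whole mapping network into an ordered ETL script.

    Statement order equals the node schedule; the script text is
    byte-identical across runs for fixed inputs.
    """
    registry = registry if registry is not None else builtin_command_registry()
    dialect = dialect or EmbeddedDialect()
    mapping.validate(registry, source_graph)

    bindings: dict[str, TableBinding] = {}
    overload_map: dict[str, list] = {}

    def bind(concept: str):
        if concept in bindings:
            return
        bindings[concept] = resolve_binding(source_graph, URIRef(concept))
        ovs = resolve_overloads(source_graph, URIRef(concept))
        if ovs:
            overload_map[concept] = ovs
            for ov in ovs:
                bind(ov.supplier_concept)

    for concept in sorted(mapping.leaf_concepts()):
        bind(concept)

    def concept_code(target: str) -> str:
        if target_graph is not None:
            code = target_graph.literal(URIRef(target), vocab.HAS_CONCEPT_CODE)
            if code:
                return code
        return local_name(target)

    statements: list[SQLStatement] = []
    final: list[SQLStatement] = []
    upstream: dict[str, str] = {}

    for target, source in sorted(mapping.simple_mappings):
        st = _import_statement(target, source, bindings, overload_map, dialect)
        statements.append(st)
        final.append(_final_load_statement(target, st.creates_table,
                                           concept_code(target), fact_table,
                                           st.node_id, dialect))
    for node in mapping.schedule_nodes():
        st = generate_node_sql(node, registry, bindings, overload_map, upstream, dialect)
        statements.append(st)
        upstream[node.id] = st.creates_table
        if node.output_concept is not None:
            final.append(_final_load_statement(node.output_concept, st.creates_table,
                                               concept_code(node.output_concept),
                                               fact_table, node.id, dialect))
    return ETLScript(statements=statements, final_load=final, dialect=dialect.name)


def execute_script(script: ETLScript, connection) -> RunReport:
    """Run an ETL script on a DB-API connection, one transaction per statement.

    Aborts on the first SQL error, naming the failing node and statement.
    The report lists the row count each statement produced.
    """
    report = RunReport()
    cur = connection.cursor()
    for st in script.all_statements:
        t0 = time.perf_counter()
        try:
            for part in st.parts:
                cur.execute(part)
            connection.commit()
        except Exception as exc:
            connection.rollback()
            raise ExecutionError(st.node_id, st.text, exc) from exc
        if st.creates_table:
            cur.execute(f"SELECT COUNT(*) FROM {st.creates_table}")
            rows = cur.fetchone()[0]
        else:
            rows = cur.rowcount if cur.rowcount is not None and cur.rowcount >= 0 else 0
        report.entries.append(StatementReport(st.node_id, rows, time.perf_counter() - t0))
    return report


def read_temp_table(connection, table: str) -> set:
    """Six-column content of a temp table as a set of tuples (for checks)."""
    cur = connection.cursor()
    cur.execute(f"SELECT {', '.join(INTERNAL_COLUMNS)} FROM {table}")
    return {tuple(row) for row in cur.fetchall()}
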