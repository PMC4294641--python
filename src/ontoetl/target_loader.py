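"""Target-side loading: star-schema DDL, concept metadata, statistics.

The target is a minimal i2b2-like star schema: a concept-metadata table
(one row per target-ontology concept, with a hierarchical path) and an
observation-fact table (one row per exported record, with patient,
concept code, dates, value and the NodeName provenance of the mapping
that produced it).  The provenance column is what makes the per-node
mapping statistics and redundancy reports possible after the fact.
"""
from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

from rdflib import URIRef
from rdflib.namespace import RDFS

from . import vocab
from .errors import MetadataError
from .mapping_algebra import MappingGraph
from .ontology_store import OntologyGraph
from .vocab import local_name

#: Star-schema DDL shipped with the package (embedded/ANSI types).
STAR_SCHEMA_DDL = (
    """CREATE TABLE IF NOT EXISTS concept_dimension (
    concept_cd   TEXT PRIMARY KEY,
    concept_path TEXT NOT NULL UNIQUE,
    name         TEXT,
    datatype     TEXT,
    unit         TEXT,
    description  TEXT
)""",
    """CREATE TABLE IF NOT EXISTS observation_fact (
    document_id TEXT,
    patient_id  TEXT NOT NULL,
    case_id     TEXT,
    concept_cd  TEXT NOT NULL,
    start_date  TEXT,
    end_date    TEXT,
    value       TEXT,
    provenance  TEXT
)""",
)

PATH_SEPARATOR = "\\"


def ensure_star_schema(connection) -> None:
    cur = connection.cursor()
    for ddl in STAR_SCHEMA_DDL:
        cur.execute(ddl)
    connection.commit()


@dataclass(frozen=True)
class TargetConceptMeta:
    path: str
    code: str
    name: str
    datatype: str = "text"
    unit: Optional[str] = None
    description: Optional[str] = None
    iri: str = ""
    is_leaf: bool = True


def build_metadata(target_graph: OntologyGraph) -> list:
    """One metadata row per target-ontology concept, in path order.

    The hierarchy comes from ``rdfs:subClassOf``; the path concatenates
    labels from root to concept with backslashes (i2b2 style).  Concept
    codes default to the IRI local name.  Colliding paths (duplicate
    sibling labels) are an error naming both IRIs.
    """
    concepts = set()
    parent: dict = {}
    for s, p, o in target_graph:
        if p == RDFS.subClassOf and isinstance(s, URIRef) and isinstance(o, URIRef):
            concepts.add(s)
            concepts.add(o)
            parent[s] = o
        elif p in (RDFS.label, vocab.HAS_CONCEPT_CODE, vocab.HAS_DATA_TYPE) and isinstance(s, URIRef):
            concepts.add(s)
    has_children = set(parent.values())

    def label(c) -> str:
        return target_graph.literal(c, RDFS.label) or local_name(c)

    def path(c) -> str:
        chain = []
        node = c
        while node is not None:
            chain.append(label(node))
            node = parent.get(node)
            if node in chain:  # defensive: cyclic subClassOf
                break
        return PATH_SEPARATOR + PATH_SEPARATOR.join(reversed(chain))

    rows = []
    by_path: dict[str, str] = {}
    for c in sorted(concepts, key=str):
        p = path(c)
        if p in by_path:
            raise MetadataError(
                f"concept path {p!r} produced by both {by_path[p]} and {c}"
            )
        by_path[p] = str(c)
        rows.append(
            TargetConceptMeta(
                path=p,
                code=target_graph.literal(c, vocab.HAS_CONCEPT_CODE) or local_name(c),
                name=label(c),
                datatype=target_graph.literal(c, vocab.HAS_DATA_TYPE) or "text",
                unit=target_graph.literal(c, vocab.HAS_UNIT),
                description=target_graph.literal(c, vocab.HAS_DESCRIPTION),
                iri=str(c),
                is_leaf=c not in has_children,
            )
        )
    rows.sort(key=lambda r: r.path)
    codes = Counter(r.code for r in rows if r.is_leaf)
    dup = [c for c, n in codes.items() if n > 1]
    if dup:
        raise MetadataError(f"leaf concept codes are not unique: {sorted(dup)}")
    return rows


def load_metadata(metadata, connection) -> int:
    ensure_star_schema(connection)
    cur = connection.cursor()
    for m in metadata:
        cur.execute(
            "INSERT OR REPLACE INTO concept_dimension "
            "(concept_cd, concept_path, name, datatype, unit, description) "
            "VALUES (?, ?, ?, ?, ?, ?)",
            (m.code, m.path, m.name, m.datatype, m.unit, m.description),
        )
    connection.commit()
    return len(metadata)


def metadata_csv(metadata) -> str:
    """Metadata export as delimited text (deterministic for a fixed ontology)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["concept_path", "concept_cd", "name", "datatype", "unit", "description"])
    for m in metadata:
        w.writerow([m.path, m.code, m.name, m.datatype, m.unit or "", m.description or ""])
    return buf.getvalue()


def load_facts(
    results: Mapping[str, object],
    connection,
    target_graph: Optional[OntologyGraph] = None,
    provenance: Optional[Mapping[str, str]] = None,
) -> dict:
    """Insert evaluator record sets as observation facts; counts per code.

    ``results`` maps target IRIs to
    :class:`~ontoetl.reference_evaluator.RecordSet`.  Every target must
    resolve to a concept code (from the target ontology, or its local
    name); an unknown concept is an error.
    """
    ensure_star_schema(connection)
    known = None
    codes: dict[str, str] = {}
    if target_graph is not None:
        known = {m.iri: m.code for m in build_metadata(target_graph)}
    cur = connection.cursor()
    counts: dict[str, int] = {}
    for target in sorted(results):
        if known is not None:
            if target not in known:
                raise MetadataError(f"target concept {target} is not in the metadata")
            code = known[target]
        else:
            code = local_name(target)
        prov = (provenance or {}).get(target, f"eval:{local_name(target)}")
        rs = results[target]
        for r in rs.records:
            cur.execute(
                "INSERT INTO observation_fact (document_id, patient_id, case_id, "
                "concept_cd, start_date, end_date, value, provenance) "
                "VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                (r.document_id, r.patient_id, r.case_id, code, r.date_start,
                 r.date_end, r.value, prov),
            )
        counts[code] = counts.get(code, 0) + len(rs.records)
    connection.commit()
    return counts


def read_facts(connection, concept_cd: Optional[str] = None) -> set:
    cur = connection.cursor()
    sql = ("SELECT document_id, patient_id, case_id, start_date, end_date, value "
           "FROM observation_fact")
    if concept_cd is not None:
        cur.execute(sql + " WHERE concept_cd = ?", (concept_cd,))
    else:
        cur.execute(sql)
    return {tuple(row) for row in cur.fetchall()}


# ---------------------------------------------------------------------------
# Mapping statistics / provenance report
# ---------------------------------------------------------------------------

@dataclass
class MappingStatistics:
    node_type_counts: dict = field(default_factory=dict)
    n_simple: int = 0
    n_complex_roots: int = 0
    n_nodes: int = 0
    #: targets fed by more than one mapping — candidate redundant source
    #: elements worth consolidating in the source system
    redundant_targets: dict = field(default_factory=dict)

    @property
    def n_mappings(self) -> int:
        return self.n_simple + self.n_complex_roots

    def as_table(self) -> str:
        lines = ["Node type      Times used", "-" * 26]
        for name in sorted(self.node_type_counts):
            lines.append(f"{name:<15}{self.node_type_counts[name]:>10}")
        lines += [
            "-" * 26,
            f"simple mappings:  {self.n_simple}",
            f"complex mappings: {self.n_complex_roots}",
            f"total mappings:   {self.n_mappings}",
        ]
        if self.redundant_targets:
            lines.append("targets with multiple mappings (redundancy candidates):")
            for t, n in sorted(self.redundant_targets.items()):
                lines.append(f"  {local_name(t)}: {n}")
        return "\n".join(lines)


def mapping_statistics(mapping: MappingGraph) -> MappingStatistics:
    """Per-node-type counts plus simple/complex totals and redundancy report."""
    counts = Counter(n.command for n in mapping.nodes)
    incoming = Counter(t for t, _ in mapping.simple_mappings)
    incoming.update(n.output_concept for n in mapping.roots())
    return MappingStatistics(
        node_type_counts=dict(counts),
        n_simple=len(mapping.simple_mappings),
        n_complex_roots=len(mapping.roots()),
        n_nodes=len(mapping.nodes),
        redundant_targets={t: n for t, n in incoming.items() if n > 1},
    )
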