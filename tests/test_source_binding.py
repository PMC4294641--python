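"""Binding resolution, fetch-SQL generation and source ontology generation."""
import sqlite3

import pytest
from rdflib import Literal, URIRef
from rdflib.namespace import RDFS

from ontoetl import (
    BindingError,
    OntoETLError,
    OntologyGraph,
    build_fetch_sql,
    generate_source_ontology,
    resolve_binding,
    resolve_overloads,
)
from ontoetl import vocab
from ontoetl.fixtures import FixtureSpec, make_gleason_fixture, make_random_emr
from ontoetl.source_binding import read_metadata_csv


def fetch_rows(conn, sql):
    return set(map(tuple, conn.execute(sql).fetchall()))


class TestResolveBinding:
    def test_gleason1_binding_matches_figure_values(self, gleason):
        b = resolve_binding(gleason.source_ontology,
                            URIRef(gleason.source_iris["Gleason1"]))
        assert b.source_table_name == "MyEMRData"
        assert b.patient_id_column == "PatID"
        assert b.value_column == "Value"
        assert b.select_filter == "Attribute = 'GL1'"
        assert b.date_start_column == "SaveDate"

    def test_binding_inherited_from_parent_form(self, gleason):
        # the table binding sits on the ProstateForm ancestor, so two
        # sibling elements resolve to the same table
        g = gleason.source_ontology
        b1 = resolve_binding(g, URIRef(gleason.source_iris["Gleason1"]))
        b2 = resolve_binding(g, URIRef(gleason.source_iris["Gleason2"]))
        assert b1.source_table_name == b2.source_table_name
        assert b1.connection_ref == b2.connection_ref

    def test_concept_without_filter_gets_empty_filter(self):
        g = OntologyGraph()
        c, t = URIRef("urn:c"), URIRef("urn:t")
        g.add((c, vocab.HAS_SOURCE_TABLE, t))
        g.add((t, vocab.HAS_SOURCE_TABLE_NAME, Literal("T")))
        g.add((t, vocab.HAS_PATIENT_ID_COLUMN, Literal("PID")))
        g.add((t, vocab.HAS_VALUE_COLUMN, Literal("VAL")))
        assert resolve_binding(g, c).select_filter == ""

    def test_unbound_concept_raises_naming_concept(self):
        g = OntologyGraph()
        with pytest.raises(BindingError, match="urn:lost"):
            resolve_binding(g, URIRef("urn:lost"))


class TestFetchSQL:
    def test_gleason1_fetch_returns_figure_record(self, gleason):
        b = resolve_binding(gleason.source_ontology,
                            URIRef(gleason.source_iris["Gleason1"]))
        sql = build_fetch_sql(b)
        rows = fetch_rows(gleason.connection, sql)
        assert rows == {("doc1", "12345", None, "2011-05-06", None, "2")}

    def test_fetch_equals_brute_force_filter_on_random_fixtures(self):
        for seed in range(3):
            for layout in ("eav", "column"):
                emr = make_random_emr(FixtureSpec(n_patients=10, seed=seed, layout=layout))
                for el in emr.elements:
                    b = resolve_binding(emr.source_ontology, URIRef(el.iri))
                    got = fetch_rows(emr.connection, build_fetch_sql(b))
                    assert got == emr.source_data[el.iri].as_tuples(), (seed, layout, el.iri)

    def test_empty_filter_emits_no_where_clause(self):
        g = OntologyGraph()
        c, t = URIRef("urn:c"), URIRef("urn:t")
        g.add((c, vocab.HAS_SOURCE_TABLE, t))
        g.add((t, vocab.HAS_SOURCE_TABLE_NAME, Literal("T")))
        g.add((t, vocab.HAS_PATIENT_ID_COLUMN, Literal("PID")))
        g.add((t, vocab.HAS_VALUE_COLUMN, Literal("VAL")))
        assert "WHERE" not in build_fetch_sql(resolve_binding(g, c))

    def test_overload_replaces_storage_date_with_biopsy_date(self, gleason):
        g = gleason.source_ontology
        concept = URIRef(gleason.source_iris["Gleason1"])
        ovs = resolve_overloads(g, concept)
        assert [(o.overloaded_column, o.supplier_concept.rsplit("#", 1)[1]) for o in ovs] == \
            [("date_start", "DateBiops")]
        bindings = {iri: resolve_binding(g, URIRef(iri)) for iri in gleason.source_iris.values()}
        sql = build_fetch_sql(bindings[str(concept)], ovs, bindings)
        rows = fetch_rows(gleason.connection, sql)
        assert rows == {("doc1", "12345", None, "2011-03-04", None, "2")}

    def test_overload_falls_back_to_storage_date_without_supplier_record(self, gleason):
        gleason.connection.execute("DELETE FROM MyEMRData WHERE Attribute = 'DATB'")
        g = gleason.source_ontology
        concept = URIRef(gleason.source_iris["Gleason1"])
        bindings = {iri: resolve_binding(g, URIRef(iri)) for iri in gleason.source_iris.values()}
        sql = build_fetch_sql(bindings[str(concept)],
                              resolve_overloads(g, concept), bindings)
        rows = fetch_rows(gleason.connection, sql)
        assert rows == {("doc1", "12345", None, "2011-05-06", None, "2")}

    def test_multiple_supplier_records_pick_smallest_value(self, gleason):
        gleason.connection.execute(
            "INSERT INTO MyEMRData VALUES ('doc1','12345',NULL,'DATB','2011-01-01','2011-05-06')")
        g = gleason.source_ontology
        concept = URIRef(gleason.source_iris["Gleason1"])
        bindings = {iri: resolve_binding(g, URIRef(iri)) for iri in gleason.source_iris.values()}
        sql = build_fetch_sql(bindings[str(concept)],
                              resolve_overloads(g, concept), bindings)
        rows = fetch_rows(gleason.connection, sql)
        assert rows == {("doc1", "12345", None, "2011-01-01", None, "2")}


META_ROWS = [
    (f"F{f}", f"Form {f}", f"F{f}E{e}", f"Element {f}.{e}", str(v), f"v{v}",
     f"Attribute = 'F{f}E{e}'")
    for f in (1, 2) for e in (1, 2, 3) for v in (1, 2)
]


class TestGenerateSourceOntology:
    def test_counts_forms_elements_values(self):
        g = generate_source_ontology(META_ROWS)
        forms = {s for s, _, o in g.query_pattern(None, RDFS.subClassOf, None)
                 if str(o).endswith("SourceRoot")}
        elements = {s for s, _, o in g.query_pattern(None, RDFS.subClassOf, None)
                    if o in forms}
        values = g.query_pattern(None, vocab.HAS_PERMISSIBLE_VALUE, None)
        assert len(forms) == 2
        assert len(elements) == 6
        assert len(values) == 12

    def test_regeneration_is_identity(self):
        assert generate_source_ontology(META_ROWS) == generate_source_ontology(META_ROWS)

    def test_elements_inherit_single_table_binding(self):
        g = generate_source_ontology(META_ROWS)
        b = resolve_binding(g, URIRef("https://ontoetl.dev/source#F1E2"))
        assert b.source_table_name == "EMRDATA"
        assert b.select_filter == "Attribute = 'F1E2'"

    def test_conflicting_duplicate_element_rejected(self):
        rows = META_ROWS + [("F1", "Form 1", "F1E1", "Different label", "9", "v9", "x")]
        with pytest.raises(OntoETLError, match="duplicate element"):
            generate_source_ontology(rows)

    def test_empty_metadata_rejected(self):
        with pytest.raises(OntoETLError):
            generate_source_ontology([])

    def test_csv_round_trip(self, tmp_path):
        import csv
        p = tmp_path / "meta.csv"
        with open(p, "w", newline="") as fh:
            csv.writer(fh).writerows(META_ROWS)
        assert read_metadata_csv(p) == [tuple(r) for r in META_ROWS]
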