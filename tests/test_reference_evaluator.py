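"""Node and network semantics of the in-memory reference evaluator."""
import pytest

from ontoetl import (
    Constant,
    ConceptRef,
    EvaluationError,
    MappingGraph,
    MappingNode,
    NodeRef,
    Record,
    RecordSet,
    apply_overloads,
    eval_network,
    eval_node,
)
from ontoetl.source_binding import ColumnOverload


def rs(concept, *items):
    """RecordSet from (doc, value) or (doc, value, date_start) tuples."""
    records = []
    for item in items:
        doc, value = item[0], item[1]
        ds = item[2] if len(item) > 2 else None
        records.append(Record(document_id=doc, patient_id="p1", date_start=ds, value=value))
    return RecordSet(concept, records)


def node(cmd, op1="A", op2="B"):
    def as_op(x):
        if isinstance(x, (Constant, NodeRef, ConceptRef)):
            return x
        return ConceptRef(x)
    return MappingNode("n1", cmd, as_op(op1), as_op(op2))


def values(result):
    return {(r.document_id, r.value) for r in result.records}


class TestNodeSemantics:
    def test_add_sums_numeric_values_per_document(self):
        out = eval_node(node("ADD"), {"A": rs("A", ("doc1", "2")),
                                      "B": rs("B", ("doc1", "3"))})
        assert values(out) == {("doc1", "5")}

    def test_add_joins_on_document_not_patient(self):
        out = eval_node(node("ADD"), {"A": rs("A", ("doc1", "2")),
                                      "B": rs("B", ("doc2", "3"))})
        assert len(out) == 0

    @pytest.mark.parametrize("a,b,strict_out,tolerant_out", [
        (("doc1", "2"), ("doc1", "3"), {("doc1", "5")}, {("doc1", "5")}),
        (("doc1", "2"), None, set(), {("doc1", "2")}),
        (None, ("doc1", "3"), set(), {("doc1", "3")}),
        (None, None, set(), set()),
    ])
    def test_strict_drops_tolerant_substitutes_neutral_zero(self, a, b, strict_out, tolerant_out):
        inputs = {"A": rs("A", *([a] if a else [])), "B": rs("B", *([b] if b else []))}
        assert values(eval_node(node("ADD"), inputs)) == strict_out
        assert values(eval_node(node("ADD_TOLERANT"), inputs)) == tolerant_out

    def test_tolerant_multiply_neutral_is_one(self):
        out = eval_node(node("MULTIPLY_TOLERANT"), {"A": rs("A", ("doc1", "4")),
                                                    "B": rs("B")})
        assert values(out) == {("doc1", "4")}

    def test_concat_substitutes_empty_string(self):
        inputs = {"A": rs("A", ("doc1", "x")), "B": rs("B", ("doc2", "y"))}
        out = eval_node(node("CONCAT"), inputs)
        assert values(out) == {("doc1", "x"), ("doc2", "y")}

    def test_if_returns_operand2_where_operand1_true(self):
        inputs = {"A": rs("A", ("doc1", "TRUE"), ("doc2", "FALSE")),
                  "B": rs("B", ("doc1", "a"), ("doc2", "b"))}
        assert values(eval_node(node("IF"), inputs)) == {("doc1", "a")}

    def test_notexists_emits_true_per_operand2_document(self):
        inputs = {"A": rs("A"), "B": rs("B", ("doc1", "x"))}
        assert values(eval_node(node("NOTEXISTS"), inputs)) == {("doc1", "TRUE")}
        inputs = {"A": rs("A", ("doc1", "y")), "B": rs("B", ("doc1", "x"))}
        assert values(eval_node(node("NOTEXISTS"), inputs)) == set()

    def test_exists_requires_equal_values(self):
        inputs = {"A": rs("A", ("doc1", "pT2")), "B": rs("B", ("doc1", "pT2"))}
        assert values(eval_node(node("EXISTS"), inputs)) == {("doc1", "TRUE")}
        inputs = {"A": rs("A", ("doc1", "pT2")), "B": rs("B", ("doc1", "pT3"))}
        assert values(eval_node(node("EXISTS"), inputs)) == set()

    @pytest.mark.parametrize("v1,v2,expect", [
        ("3", "2", {("doc1", "TRUE")}),
        ("2", "3", set()),
        ("10", "9", {("doc1", "TRUE")}),   # numeric, not lexicographic
        ("abc", "abd", set()),             # lexicographic for non-numbers
        ("b", "a", {("doc1", "TRUE")}),
    ])
    def test_greater_numeric_aware(self, v1, v2, expect):
        inputs = {"A": rs("A", ("doc1", v1)), "B": rs("B", ("doc1", v2))}
        assert values(eval_node(node("GREATER"), inputs)) == expect

    def test_greatervt_passes_when_operand1_absent(self):
        inputs = {"A": rs("A"), "B": rs("B", ("doc1", "5"))}
        assert values(eval_node(node("GREATERVT"), inputs)) == {("doc1", "TRUE")}
        inputs = {"A": rs("A", ("doc1", "4")), "B": rs("B", ("doc1", "5"))}
        assert values(eval_node(node("GREATERVT"), inputs)) == set()

    def test_constant_operand_expands_per_document(self):
        out = eval_node(node("GREATER", "A", Constant("2")),
                        {"A": rs("A", ("doc1", "3"), ("doc2", "1"))})
        assert values(out) == {("doc1", "TRUE")}

    def test_add_commutative_on_full_operands_if_not(self):
        inputs = {"A": rs("A", ("doc1", "2")), "B": rs("B", ("doc1", "3"))}
        fwd = eval_node(node("ADD", "A", "B"), inputs)
        rev = eval_node(node("ADD", "B", "A"), inputs)
        assert values(fwd) == values(rev)
        inputs = {"A": rs("A", ("doc1", "TRUE")), "B": rs("B", ("doc1", "x"))}
        assert values(eval_node(node("IF", "A", "B"), inputs)) == {("doc1", "x")}
        assert values(eval_node(node("IF", "B", "A"), inputs)) == set()

    def test_non_numeric_arithmetic_skips_row_or_raises_in_strict(self):
        inputs = {"A": rs("A", ("doc1", "oops")), "B": rs("B", ("doc1", "3"))}
        assert len(eval_node(node("ADD"), inputs)) == 0
        with pytest.raises(EvaluationError):
            eval_node(node("ADD"), inputs, strict=True)

    def test_result_deduplicated(self):
        inputs = {"A": rs("A", ("doc1", "2"), ("doc1", "2")),
                  "B": rs("B", ("doc1", "3"))}
        assert len(eval_node(node("ADD"), inputs)) == 1

    def test_dates_follow_command_date_source(self):
        inputs = {"A": rs("A", ("doc1", "2", "2011-03-04")),
                  "B": rs("B", ("doc1", "3", "2012-01-01"))}
        add = eval_node(node("ADD"), inputs)       # dates from OP1
        assert add.records[0].date_start == "2011-03-04"
        inputs_if = {"A": rs("A", ("doc1", "TRUE", "2011-03-04")),
                     "B": rs("B", ("doc1", "x", "2012-01-01"))}
        iff = eval_node(node("IF"), inputs_if)     # dates from OP2
        assert iff.records[0].date_start == "2012-01-01"


class TestOverloads:
    def test_supplier_value_replaces_date_start(self):
        base = RecordSet("A", [Record("doc1", "p", date_start="2011-05-06", value="2")])
        supplier = {"S": RecordSet("S", [Record("doc1", "p", value="2011-03-04")])}
        out = apply_overloads(base, [ColumnOverload("A", "date_start", "S")], supplier)
        assert out.records[0].date_start == "2011-03-04"

    def test_missing_supplier_keeps_original(self):
        base = RecordSet("A", [Record("doc1", "p", date_start="2011-05-06", value="2")])
        out = apply_overloads(base, [ColumnOverload("A", "date_start", "S")],
                              {"S": RecordSet("S", [])})
        assert out.records[0].date_start == "2011-05-06"

    def test_multiple_supplier_records_take_smallest(self):
        base = RecordSet("A", [Record("doc1", "p", date_start="x", value="2")])
        supplier = {"S": RecordSet("S", [Record("doc1", "p", value="b"),
                                         Record("doc1", "p", value="a")])}
        out = apply_overloads(base, [ColumnOverload("A", "date_start", "S")], supplier)
        assert out.records[0].date_start == "a"


class TestNetwork:
    def test_gleason_network_sums_when_total_absent(self, gleason):
        res = eval_network(gleason.mapping, gleason.source_data,
                           source_graph=gleason.source_ontology)
        (rec,) = res[gleason.target_iri].records
        assert rec.value == "5"
        assert rec.date_start == "2011-03-04"
        assert rec.patient_id == "12345"

    def test_gleason_network_prefers_documented_total(self):
        from ontoetl.fixtures import make_gleason_fixture
        fx = make_gleason_fixture(include_gleason3="4")
        res = eval_network(fx.mapping, fx.source_data, source_graph=fx.source_ontology)
        (rec,) = res[fx.target_iri].records
        assert rec.value == "4"

    def test_no_mappings_yields_empty_output(self):
        assert eval_network(MappingGraph(), {}) == {}

    def test_two_valid_schedules_agree(self, gleason):
        res1 = eval_network(gleason.mapping, gleason.source_data,
                            source_graph=gleason.source_ontology)
        # reversed node list -> different (still valid) ready-set ordering
        reordered = MappingGraph(
            simple_mappings=list(gleason.mapping.simple_mappings),
            nodes=list(reversed(gleason.mapping.nodes)),
        )
        res2 = eval_network(reordered, gleason.source_data,
                            source_graph=gleason.source_ontology)
        assert {k: v.as_tuples() for k, v in res1.items()} == \
               {k: v.as_tuples() for k, v in res2.items()}
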