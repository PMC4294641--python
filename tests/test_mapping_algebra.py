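"""Expression parsing, triple round-trips, scheduling, command registry."""
import random

import pytest

from ontoetl import (
    Constant,
    ConceptRef,
    ExpressionParseError,
    MappingError,
    MappingGraph,
    MappingNode,
    NodeRef,
    SchedulingError,
    builtin_command_registry,
    parse_mapping_expression,
    parse_mapping_file,
    unparse_mapping,
)
from ontoetl.mapping_algebra import commands_from_graph, register_command, CommandType


TABLE1_COMMANDS = ["ADD", "EQUALS", "GREATER", "GREATERVT", "EXISTS", "NOTEXISTS", "IF"]


class TestRegistry:
    def test_contains_the_seven_core_operators(self, registry):
        assert set(TABLE1_COMMANDS) <= set(registry)

    def test_strict_add_requires_both_operands(self, registry):
        add = registry["ADD"]
        assert add.join == "inner"
        assert "IS NOT NULL" in add.select_filter
        assert not add.tolerant

    def test_tolerant_arithmetic_neutral_elements(self, registry):
        assert registry["ADD_TOLERANT"].neutral_element == "0"
        assert registry["MULTIPLY_TOLERANT"].neutral_element == "1"
        assert registry["CONCAT"].neutral_element == ""

    def test_duplicate_registration_rejected(self, registry):
        with pytest.raises(MappingError):
            register_command(dict(registry), registry["ADD"])

    def test_user_command_types_loadable_from_triples(self, registry):
        from rdflib import Literal, URIRef
        from ontoetl import OntologyGraph, vocab
        g = OntologyGraph()
        c = URIRef("urn:cmd:SUBTRACT")
        g.add((c, vocab.HAS_OUTPUT_TRANSFORMATION,
               Literal("CAST({op1} AS NUMERIC) - CAST({op2} AS NUMERIC)")))
        g.add((c, vocab.HAS_CATEGORY, Literal("arithmetic")))
        reg = commands_from_graph(g, dict(registry))
        assert reg["SUBTRACT"].category == "arithmetic"


class TestParse:
    def test_fig_style_conditional_expression(self):
        g = parse_mapping_expression(
            "Gleason3: IF (NOTEXISTS Gleason3 Gleason1) (ADD Gleason1 Gleason2)")
        assert [n.command for n in g.nodes] == ["IF", "NOTEXISTS", "ADD"]
        root = g.nodes[0]
        assert root.output_concept.endswith("Gleason3")
        assert isinstance(root.operand1, NodeRef)
        assert g.node_by_id()[root.operand1.node_id].command == "NOTEXISTS"
        assert g.node_by_id()[root.operand2.node_id].command == "ADD"
        # operand order is significant
        ne = g.node_by_id()[root.operand1.node_id]
        assert ne.operand1 == ConceptRef("https://ontoetl.dev/adhoc#Gleason3")
        assert ne.operand2 == ConceptRef("https://ontoetl.dev/adhoc#Gleason1")

    def test_bare_concept_is_simple_import(self):
        g = parse_mapping_expression("T: S")
        assert g.nodes == []
        assert g.simple_mappings == [
            ("https://ontoetl.dev/adhoc#T", "https://ontoetl.dev/adhoc#S")]

    def test_quoted_literal_becomes_constant(self):
        g = parse_mapping_expression('T: (GREATER Gleason3 "2")')
        (node,) = g.nodes
        assert node.command == "GREATER"
        assert node.operand2 == Constant("2")

    def test_command_names_case_insensitive(self):
        g = parse_mapping_expression("T: (add A B)")
        assert g.nodes[0].command == "ADD"

    @pytest.mark.parametrize("text,fragment", [
        ("T: (FROBNICATE A B)", "unknown command"),
        ("T: (ADD A)", "two operands"),
        ("T: (ADD A B C)", "two operands"),
        ("T: (ADD A B", "two operands"),
        ("T (ADD A B)", "Target"),
        ("T: (ADD A B) junk", "trailing"),
    ])
    def test_malformed_expressions_raise_with_position(self, text, fragment):
        with pytest.raises(ExpressionParseError, match=fragment):
            parse_mapping_expression(text)

    def test_file_parse_skips_comments_and_merges(self):
        text = "# header\nT1: S1\n\nT2: (ADD S1 S2)  # inline\n"
        g = parse_mapping_file(text)
        assert len(g.simple_mappings) == 1 and len(g.nodes) == 1


class TestTripleRoundTrip:
    def test_simple_import_round_trips(self):
        g = parse_mapping_expression("T: S")
        assert MappingGraph.from_triples(g.to_triples()).simple_mappings == g.simple_mappings

    def test_cascade_round_trips_with_expected_shape(self, gleason):
        triples = gleason.mapping.to_triples()
        from ontoetl import vocab
        assert len(triples.query_pattern(None, vocab.HAS_COMMAND_TYPE, None)) == 3
        n_operand_edges = len(triples.query_pattern(None, vocab.HAS_OPERAND1, None)) + \
            len(triples.query_pattern(None, vocab.HAS_OPERAND2, None))
        assert n_operand_edges == 6
        back = MappingGraph.from_triples(triples)
        assert sorted(n.command for n in back.nodes) == ["ADD", "IF", "NOTEXISTS"]
        assert back.simple_mappings == sorted(gleason.mapping.simple_mappings)

    def test_double_operand1_rejected(self):
        from rdflib import URIRef
        from ontoetl import OntologyGraph, vocab
        g = OntologyGraph()
        node = URIRef("urn:n1")
        g.add((node, vocab.HAS_COMMAND_TYPE, vocab.OE.ADD))
        g.add((node, vocab.HAS_OPERAND1, URIRef("urn:a")))
        g.add((node, vocab.HAS_OPERAND1, URIRef("urn:b")))
        g.add((node, vocab.HAS_OPERAND2, URIRef("urn:c")))
        with pytest.raises(MappingError, match="hasOperand1"):
            MappingGraph.from_triples(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_parse_to_triples_and_back_preserves_semantics(self, seed, registry):
        expr = random_expression(random.Random(seed), depth=seed % 5)
        g1 = parse_mapping_expression(f"T: {expr}", registry=registry)
        g2 = MappingGraph.from_triples(g1.to_triples())
        assert trees_isomorphic(g1, g2)
        # unparse -> reparse is also stable
        g3 = parse_mapping_file(unparse_mapping(g1), registry=registry)
        assert trees_isomorphic(g1, g3)


def random_expression(rng: random.Random, depth: int, top: bool = True) -> str:
    commands = ["ADD", "EQUALS", "GREATER", "IF", "CONCAT", "NOTEXISTS"]
    if depth <= 0:
        if not top and rng.random() < 0.3:
            return f'"{rng.randrange(10)}"'  # a bare constant is no mapping
        return f"C{rng.randrange(8)}"
    cmd = rng.choice(commands)
    a = random_expression(rng, rng.randrange(depth), top=False)
    b = random_expression(rng, rng.randrange(depth), top=False)
    if a.startswith('"') and b.startswith('"'):
        b = "C0"
    return f"({cmd} {a} {b})"


def canonical(graph: MappingGraph, operand):
    if isinstance(operand, NodeRef):
        n = graph.node_by_id()[operand.node_id]
        return (n.command,
                canonical(graph, n.operand1),
                canonical(graph, n.operand2))
    return operand


def trees_isomorphic(g1: MappingGraph, g2: MappingGraph) -> bool:
    r1 = [n for n in g1.nodes if n.output_concept]
    r2 = [n for n in g2.nodes if n.output_concept]
    if len(r1) != len(r2) or sorted(g1.simple_mappings) != sorted(g2.simple_mappings):
        return False
    c1 = sorted(map(repr, (canonical(g1, NodeRef(n.id)) for n in r1)))
    c2 = sorted(map(repr, (canonical(g2, NodeRef(n.id)) for n in r2)))
    return c1 == c2


class TestSchedule:
    def test_cascade_schedules_if_last(self, gleason):
        order = [n.command for n in gleason.mapping.schedule_nodes()]
        assert order[-1] == "IF"
        assert set(order[:2]) == {"NOTEXISTS", "ADD"}

    def test_empty_graph_empty_schedule(self):
        assert MappingGraph().schedule_nodes() == []

    def test_cycle_rejected_listing_nodes(self):
        g = MappingGraph(nodes=[
            MappingNode("a", "ADD", NodeRef("b"), ConceptRef("urn:x")),
            MappingNode("b", "ADD", NodeRef("a"), ConceptRef("urn:x")),
        ])
        with pytest.raises(SchedulingError) as err:
            g.schedule_nodes()
        assert set(err.value.cycle_nodes) == {"a", "b"}

    @pytest.mark.parametrize("seed", range(20))
    def test_random_dags_schedule_is_valid_topological_order(self, seed):
        g = random_dag(seed)
        order = [n.id for n in g.schedule_nodes()]
        assert sorted(order) == sorted(n.id for n in g.nodes)
        position = {nid: i for i, nid in enumerate(order)}
        for n in g.nodes:
            for op in n.operands:
                if isinstance(op, NodeRef):
                    assert position[op.node_id] < position[n.id]

    def test_schedule_deterministic(self):
        g = random_dag(3)
        assert [n.id for n in g.schedule_nodes()] == [n.id for n in g.schedule_nodes()]


def random_dag(seed: int, n_nodes: int = 12) -> MappingGraph:
    rng = random.Random(seed)
    nodes = []
    for i in range(n_nodes):
        def operand():
            if nodes and rng.random() < 0.6:
                return NodeRef(rng.choice(nodes).id)
            return ConceptRef(f"urn:leaf{rng.randrange(5)}")
        op1, op2 = operand(), operand()
        nodes.append(MappingNode(f"n{rng.randrange(1000)}_{i}", "ADD", op1, op2))
    return MappingGraph(nodes=nodes)


class TestValidation:
    def test_hierarchical_level_mapping_rejected(self, gleason):
        # mapping a whole form (which has narrower concepts) must fail
        form_iri = gleason.source_iris["Gleason1"].rsplit("#", 1)[0] + "#ProstateForm"
        g = MappingGraph(simple_mappings=[("urn:t", form_iri)])
        with pytest.raises(MappingError, match="hierarchical"):
            g.validate(source_graph=gleason.source_ontology)

    def test_double_constant_node_rejected(self, registry):
        g = MappingGraph(nodes=[MappingNode("n", "ADD", Constant("1"), Constant("2"))])
        with pytest.raises(MappingError, match="constants"):
            g.validate(registry)

    def test_unknown_command_rejected(self, registry):
        g = MappingGraph(nodes=[
            MappingNode("n", "NOPE", ConceptRef("urn:a"), ConceptRef("urn:b"))])
        with pytest.raises(MappingError, match="unknown command"):
            g.validate(registry)
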