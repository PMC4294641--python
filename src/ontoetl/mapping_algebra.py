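"""The mapping algebra: binary transformation nodes between ontologies.

A mapping network connects source concepts to target concepts.  *Simple*
mappings (``hasImport``) copy a record set unchanged.  *Complex* mappings
are expression trees of intermediate nodes, each with a command type and
exactly two ordered operands (``hasOperand1``/``hasOperand2`` — ordering
makes non-commutative operations expressible).  Operands are source
concepts, constants, or other nodes; cascading nodes yields arbitrary
transformations, e.g.::

    Gleason3: IF (NOTEXISTS Gleason3 Gleason1) (ADD Gleason1 Gleason2)

— "if no Gleason 3 was documented, export the sum of Gleason 1 and 2".

Each command type carries the SQL fragments spliced into the generated
statement (output transformation and select filter over the placeholders
OP1/OP2), the operand whose timestamps the result inherits, and — for
tolerant variants — the neutral element substituted for a missing operand.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Union

from rdflib import Literal, URIRef

from . import vocab
from .errors import (
    ExpressionParseError,
    MappingError,
    SchedulingError,
    UnknownConceptError,
)
from .ontology_store import OntologyGraph
from .vocab import local_name

# ---------------------------------------------------------------------------
# Command types
# ---------------------------------------------------------------------------

#: How the two operand record sets are combined on the document key.
JOIN_INNER = "inner"        # strict: both operands must have a record
JOIN_OUTER = "outer"        # tolerant: either side may be missing
JOIN_OP2_LEFT = "op2_left"  # operand-2 driven: operand 1 may be absent


@dataclass(frozen=True)
class CommandType:
    """Declarative processing definition shared by all nodes of one type.

    ``output_transformation`` and ``select_filter`` are SQL fragments over
    the placeholders ``{op1}``/``{op2}`` (the operands' Value columns),
    ``{op1_gt_op2}`` (dialect-supplied numeric-aware comparison) and
    ``{op1_absent}`` (true when operand 1 contributed no record).
    """

    name: str
    category: str  # arithmetic | relational | string | control
    output_transformation: str
    select_filter: str = ""
    date_value_source: str = "OP1"  # OP1 | OP2
    join: str = JOIN_INNER
    tolerant: bool = False
    neutral_element: Optional[str] = None

    def __post_init__(self):
        if self.tolerant and self.neutral_element is None and self.join == JOIN_OUTER:
            raise MappingError(f"tolerant command {self.name} needs a neutral element")
        if self.date_value_source not in ("OP1", "OP2"):
            raise MappingError(f"{self.name}: hasDateValue must be OP1 or OP2")


def _strict_arith(name: str, op: str) -> CommandType:
    return CommandType(
        name=name,
        category="arithmetic",
        output_transformation=f"CAST({{op1}} AS NUMERIC) {op} CAST({{op2}} AS NUMERIC)",
        select_filter="{op1} IS NOT NULL AND {op2} IS NOT NULL",
    )


def _tolerant_arith(name: str, op: str, neutral: str) -> CommandType:
    return CommandType(
        name=name,
        category="arithmetic",
        output_transformation=(
            f"CAST(COALESCE({{op1}}, '{neutral}') AS NUMERIC) {op} "
            f"CAST(COALESCE({{op2}}, '{neutral}') AS NUMERIC)"
        ),
        join=JOIN_OUTER,
        tolerant=True,
        neutral_element=neutral,
    )


def builtin_command_registry() -> dict:
    """The built-in command types, keyed by canonical (uppercase) name.

    The seven core operators (ADD, EQUALS, GREATER, GREATERVT, EXISTS,
    NOTEXISTS, IF) cover arithmetic, relational and control processing;
    tolerant arithmetic variants and string concatenation extend them.
    User ontologies can register further command types via
    :func:`register_command` / :func:`commands_from_graph`.
    """
    commands = [
        _strict_arith("ADD", "+"),
        _strict_arith("MULTIPLY", "*"),
        _tolerant_arith("ADD_TOLERANT", "+", "0"),
        _tolerant_arith("MULTIPLY_TOLERANT", "*", "1"),
        CommandType(
            name="CONCAT",
            category="string",
            output_transformation="COALESCE({op1}, '') || COALESCE({op2}, '')",
            join=JOIN_OUTER,
            tolerant=True,
            neutral_element="",
        ),
        CommandType(
            name="EQUALS",
            category="relational",
            output_transformation="'TRUE'",
            select_filter="{op1} = {op2}",
        ),
        CommandType(
            name="GREATER",
            category="relational",
            output_transformation="'TRUE'",
            select_filter="{op1_gt_op2}",
        ),
        CommandType(
            # "operand 1 can be NULL": used for temporal first/last-value
            # selection, where the absence of a competing value must not
            # block the selection — an absent operand 1 therefore passes.
            name="GREATERVT",
            category="relational",
            output_transformation="'TRUE'",
            select_filter="({op1_absent} OR {op1_gt_op2})",
            join=JOIN_OP2_LEFT,
            date_value_source="OP2",
            tolerant=True,
        ),
        CommandType(
            name="EXISTS",
            category="relational",
            output_transformation="'TRUE'",
            select_filter="{op1} = {op2}",
        ),
        CommandType(
            # Operand 2 supplies the entities (documents/records) to emit,
            # which is why a second operand is required at all.
            name="NOTEXISTS",
            category="relational",
            output_transformation="'TRUE'",
            select_filter="{op1_absent}",
            join=JOIN_OP2_LEFT,
            date_value_source="OP2",
            tolerant=True,
        ),
        CommandType(
            name="IF",
            category="control",
            output_transformation="{op2}",
            select_filter="{op1} = 'TRUE'",
            date_value_source="OP2",
        ),
    ]
    return {c.name: c for c in commands}


def register_command(registry: dict, command: CommandType) -> dict:
    if command.name in registry:
        raise MappingError(f"command type {command.name} already registered")
    registry[command.name] = command
    return registry


def commands_from_graph(graph: OntologyGraph, registry: dict) -> dict:
    """Extend a registry with command types declared as triples.

    A command resource carries hasOutputTransformation (required),
    hasSelectFilter, hasDateValue, hasJoinKind, hasNeutralElement and
    hasCategory.  Re-declaring a built-in is an error.
    """
    subjects = {s for s, _, _ in
                graph.query_pattern(None, vocab.HAS_OUTPUT_TRANSFORMATION, None)}
    for s in sorted(subjects, key=str):
        cmd = CommandType(
            name=local_name(s).upper(),
            category=graph.literal(s, vocab.HAS_CATEGORY) or "user",
            output_transformation=graph.literal(s, vocab.HAS_OUTPUT_TRANSFORMATION) or "",
            select_filter=graph.literal(s, vocab.HAS_SELECT_FILTER) or "",
            date_value_source=graph.literal(s, vocab.HAS_DATE_VALUE) or "OP1",
            join=graph.literal(s, vocab.HAS_JOIN_KIND) or JOIN_INNER,
            tolerant=graph.literal(s, vocab.HAS_NEUTRAL_ELEMENT) is not None,
            neutral_element=graph.literal(s, vocab.HAS_NEUTRAL_ELEMENT),
        )
        register_command(registry, cmd)
    return registry


# ---------------------------------------------------------------------------
# Operands and nodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptRef:
    """Operand referring to a source concept's record set."""

    iri: str


@dataclass(frozen=True)
class NodeRef:
    """Operand referring to an upstream mapping node's output."""

    node_id: str


@dataclass(frozen=True)
class Constant:
    """Operand carrying a literal value (a virtual record per joined document)."""

    value: str


Operand = Union[ConceptRef, NodeRef, Constant]


@dataclass(frozen=True)
class MappingNode:
    id: str
    command: str  # canonical command-type name
    operand1: Operand
    operand2: Operand
    output_concept: Optional[str] = None  # target IRI when this is a mapping root

    @property
    def operands(self):
        return (self.operand1, self.operand2)


@dataclass
class MappingGraph:
    """A whole mapping network: simple imports plus complex node trees."""

    simple_mappings: list = field(default_factory=list)  # [(target IRI, source IRI)]
    nodes: list = field(default_factory=list)            # [MappingNode]

    def node_by_id(self) -> dict:
        return {n.id: n for n in self.nodes}

    def roots(self) -> list:
        return [n for n in self.nodes if n.output_concept is not None]

    def leaf_concepts(self) -> set:
        out = {src for _, src in self.simple_mappings}
        for n in self.nodes:
            for op in n.operands:
                if isinstance(op, ConceptRef):
                    out.add(op.iri)
        return out

    # -- validation ----------------------------------------------------------
    def validate(self, registry: Optional[dict] = None,
                 source_graph: Optional[OntologyGraph] = None) -> None:
        """Raise :class:`MappingError` on any structural defect.

        With a source ontology supplied, operands referring to concepts
        that have narrower concepts (a whole form or class) are rejected:
        mappings at hierarchical levels are not supported.
        """
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise MappingError("duplicate mapping node ids")
        known = set(ids)
        for n in self.nodes:
            if registry is not None and n.command not in registry:
                raise MappingError(f"node {n.id}: unknown command type {n.command}")
            if isinstance(n.operand1, Constant) and isinstance(n.operand2, Constant):
                raise MappingError(
                    f"node {n.id}: both operands are constants; at least one "
                    "operand must supply records"
                )
            for op in n.operands:
                if isinstance(op, NodeRef) and op.node_id not in known:
                    raise MappingError(f"node {n.id}: operand references unknown node {op.node_id}")
        self.schedule_nodes()  # raises SchedulingError on cycles
        if source_graph is not None:
            from rdflib.namespace import RDFS
            for concept in sorted(self.leaf_concepts()):
                children = source_graph.query_pattern(None, RDFS.subClassOf, URIRef(concept))
                if children:
                    raise MappingError(
                        f"concept {concept} has narrower concepts; mappings at "
                        "hierarchical class levels are not supported — map the "
                        "leaf elements individually"
                    )

    # -- scheduling ----------------------------------------------------------
    def schedule_nodes(self) -> list:
        """Deterministic topological order of the nodes.

        A node is ready once both operands' data are available; source
        concepts and constants are always available.  Among ready nodes the
        smallest id runs first (stable total order), so the generated ETL
        script is reproducible even though any valid order would produce
        identical data.
        """
        deps = {
            n.id: {op.node_id for op in n.operands if isinstance(op, NodeRef)}
            for n in self.nodes
        }
        by_id = self.node_by_id()
        remaining = dict(deps)
        order = []
        while remaining:
            ready = sorted(nid for nid, d in remaining.items() if not d)
            if not ready:
                raise SchedulingError(sorted(remaining))
            for nid in ready:
                order.append(by_id[nid])
                del remaining[nid]
            done = set(n.id for n in order)
            for d in remaining.values():
                d -= done
        return order

    # -- triple (de)serialization --------------------------------------------
    def to_triples(self, base_iri: str = "https://ontoetl.dev/mapping#") -> OntologyGraph:
        g = OntologyGraph()
        base = base_iri.rstrip("#/") + "#"

        def operand_term(node_id: str, slot: int, op: Operand):
            if isinstance(op, ConceptRef):
                return URIRef(op.iri)
            if isinstance(op, NodeRef):
                return URIRef(base + op.node_id)
            const = URIRef(f"{base}const_{node_id}_op{slot}")
            g.add((const, vocab.HAS_CONSTANT_VALUE, Literal(op.value)))
            return const

        for target, source in sorted(self.simple_mappings):
            g.add((URIRef(target), vocab.HAS_IMPORT, URIRef(source)))
        for n in self.nodes:
            node = URIRef(base + n.id)
            g.add((node, vocab.HAS_COMMAND_TYPE, vocab.OE[n.command]))
            g.add((node, vocab.HAS_OPERAND1, operand_term(n.id, 1, n.operand1)))
            g.add((node, vocab.HAS_OPERAND2, operand_term(n.id, 2, n.operand2)))
            if n.output_concept is not None:
                g.add((URIRef(n.output_concept), vocab.HAS_IMPORT, node))
        return g

    @classmethod
    def from_triples(cls, g: OntologyGraph) -> "MappingGraph":
        node_iris = {s for s, _, _ in g.query_pattern(None, vocab.HAS_COMMAND_TYPE, None)}

        def as_operand(term) -> Operand:
            if term in node_iris:
                return NodeRef(local_name(term))
            const = g.literal(term, vocab.HAS_CONSTANT_VALUE)
            if const is not None:
                return Constant(const)
            if isinstance(term, Literal):
                return Constant(str(term))
            return ConceptRef(str(term))

        outputs = {}
        simple = []
        for target, _, obj in g.query_pattern(None, vocab.HAS_IMPORT, None):
            if obj in node_iris:
                outputs[local_name(obj)] = str(target)
            else:
                simple.append((str(target), str(obj)))

        nodes = []
        for iri in sorted(node_iris, key=str):
            nid = local_name(iri)
            cmd = g.value(iri, vocab.HAS_COMMAND_TYPE)
            if cmd is None:  # pragma: no cover — subjects come from this pattern
                raise MappingError(f"node {nid}: missing command type")
            ops = []
            for pred in (vocab.HAS_OPERAND1, vocab.HAS_OPERAND2):
                edges = g.query_pattern(iri, pred, None)
                if len(edges) != 1:
                    raise MappingError(
                        f"node {nid}: {len(edges)} {local_name(pred)} edges; exactly one required"
                    )
                ops.append(as_operand(edges[0][2]))
            nodes.append(
                MappingNode(
                    id=nid,
                    command=local_name(cmd).upper(),
                    operand1=ops[0],
                    operand2=ops[1],
                    output_concept=outputs.get(nid),
                )
            )
        return cls(simple_mappings=sorted(simple), nodes=nodes)


# ---------------------------------------------------------------------------
# Prefix-notation expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\() |
        (?P<rparen>\)) |
        (?P<quoted>"(?:[^"\\]|\\.)*") |
        (?P<colon>:) |
        (?P<name>[^\s()":]+)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str, line_no: int):
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise ExpressionParseError(f"unexpected character {text[pos]!r}", line_no, pos + 1)
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "quoted":
            value = value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
        tokens.append((kind, value, m.start(kind) + 1))
        pos = m.end()
    return tokens


class NameResolver:
    """Resolve bare concept names in expressions against loaded ontologies.

    A name matches a concept whose IRI local name or ``rdfs:label`` equals
    it exactly.  Targets resolve against the target ontology, operands
    against the source ontology.  Without ontologies, names pass through
    under a default namespace (useful for unit tests and ad-hoc graphs).
    """

    def __init__(self, source_graph: Optional[OntologyGraph] = None,
                 target_graph: Optional[OntologyGraph] = None,
                 default_base: str = "https://ontoetl.dev/adhoc#"):
        self._source = self._index(source_graph)
        self._target = self._index(target_graph)
        self._base = default_base

    @staticmethod
    def _index(graph: Optional[OntologyGraph]):
        if graph is None:
            return None
        from rdflib.namespace import RDFS
        index: dict[str, set] = {}
        concepts = set()
        for s, p, o in graph:
            if isinstance(s, URIRef):
                concepts.add(s)
            if isinstance(o, URIRef) and p == RDFS.subClassOf:
                concepts.add(o)
        for c in concepts:
            index.setdefault(local_name(c), set()).add(str(c))
        for s, _, o in graph.query_pattern(None, RDFS.label, None):
            if isinstance(s, URIRef):
                index.setdefault(str(o), set()).add(str(s))
        return index

    def _lookup(self, index, name: str, side: str) -> str:
        if index is None:
            return self._base + name
        hits = sorted(index.get(name, ()))
        if not hits:
            raise UnknownConceptError(f"unknown {side} concept {name!r}")
        if len(hits) > 1:
            raise UnknownConceptError(f"{side} concept name {name!r} is ambiguous: {hits}")
        return hits[0]

    def target(self, name: str) -> str:
        return self._lookup(self._target, name, "target")

    def source(self, name: str) -> str:
        return self._lookup(self._source, name, "source")


def parse_mapping_expression(
    text: str,
    resolver: Optional[NameResolver] = None,
    registry: Optional[dict] = None,
    line_no: int = 1,
) -> MappingGraph:
    """Parse one ``Target: Expr`` statement in bracketed prefix notation.

    Grammar::

        Line := Target ":" Expr
        Expr := "(" CMD Arg Arg ")" | ConceptName | QuotedLiteral
        Arg  := Expr

    A bare concept on the right-hand side is a simple import mapping.
    Node ids are assigned deterministically as ``<target>_<CMD>_<n>`` in
    prefix order, so re-parsing the same line yields the same graph.
    """
    resolver = resolver or NameResolver()
    registry = registry if registry is not None else builtin_command_registry()
    tokens = _tokenize(text, line_no)
    if len(tokens) < 3 or tokens[0][0] != "name" or tokens[1][0] != "colon":
        raise ExpressionParseError("expected 'Target : expression'", line_no,
                                   tokens[0][2] if tokens else 1)
    target_name = tokens[0][1]
    target = resolver.target(target_name)
    pos = 2
    counter = [0]
    nodes: list[MappingNode] = []

    def parse_arg() -> Operand:
        nonlocal pos
        if pos >= len(tokens):
            raise ExpressionParseError("unexpected end of expression", line_no, len(text))
        kind, value, col = tokens[pos]
        if kind == "quoted":
            pos += 1
            return Constant(value)
        if kind == "name":
            pos += 1
            return ConceptRef(resolver.source(value))
        if kind == "lparen":
            return NodeRef(parse_node())
        if kind == "rparen":
            raise ExpressionParseError(
                "missing operand before ')' — every command takes exactly two operands",
                line_no, col,
            )
        raise ExpressionParseError(f"unexpected token {value!r}", line_no, col)

    def parse_node() -> str:
        nonlocal pos
        open_col = tokens[pos][2]
        pos += 1  # consume "("
        if pos >= len(tokens) or tokens[pos][0] != "name":
            raise ExpressionParseError("expected command name after '('", line_no, open_col)
        cmd_name = tokens[pos][1].upper()
        cmd_col = tokens[pos][2]
        if cmd_name not in registry:
            raise ExpressionParseError(f"unknown command {tokens[pos][1]!r}", line_no, cmd_col)
        pos += 1
        counter[0] += 1
        node_id = f"{target_name}_{cmd_name}_{counter[0]}"
        op1 = parse_arg()
        op2 = parse_arg()
        if pos >= len(tokens) or tokens[pos][0] != "rparen":
            got = tokens[pos][1] if pos < len(tokens) else "end of line"
            raise ExpressionParseError(
                f"expected ')' closing {cmd_name} (exactly two operands); got {got!r}",
                line_no, tokens[pos][2] if pos < len(tokens) else len(text),
            )
        pos += 1
        nodes.append(MappingNode(node_id, cmd_name, op1, op2))
        return node_id

    def parse_root_node() -> str:
        """Root command may appear without enclosing brackets (editor style)."""
        nonlocal pos
        cmd_name = tokens[pos][1].upper()
        cmd_col = tokens[pos][2]
        if cmd_name not in registry:
            raise ExpressionParseError(f"unknown command {tokens[pos][1]!r}", line_no, cmd_col)
        pos += 1
        counter[0] += 1
        node_id = f"{target_name}_{cmd_name}_{counter[0]}"
        op1 = parse_arg()
        op2 = parse_arg()
        nodes.append(MappingNode(node_id, cmd_name, op1, op2))
        return node_id

    kind, value, col = tokens[pos]
    if kind == "name" and pos == len(tokens) - 1:
        # degenerate expression: bare concept -> simple import
        return MappingGraph(simple_mappings=[(target, resolver.source(value))])
    if kind == "name":
        root_id = parse_root_node()
    elif kind == "lparen":
        root_id = parse_node()
    else:
        raise ExpressionParseError(f"expected '(' or a concept/command, got {value!r}",
                                   line_no, col)
    if pos != len(tokens):
        raise ExpressionParseError(
            f"trailing input after expression: {tokens[pos][1]!r}", line_no, tokens[pos][2]
        )
    nodes[-1] = replace(nodes[-1], output_concept=target)
    # nodes were appended post-order; keep a stable prefix-order by id suffix
    nodes.sort(key=lambda n: int(n.id.rsplit("_", 1)[1]))
    return MappingGraph(nodes=nodes)


def parse_mapping_file(
    text: str,
    resolver: Optional[NameResolver] = None,
    registry: Optional[dict] = None,
) -> MappingGraph:
    """Parse a whole mapping file: one statement per line, ``#`` comments."""
    merged = MappingGraph()
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip() if not _in_quotes_hash(raw) else raw.strip()
        if not line:
            continue
        part = parse_mapping_expression(line, resolver, registry, line_no=i)
        merged.simple_mappings.extend(part.simple_mappings)
        merged.nodes.extend(part.nodes)
    ids = [n.id for n in merged.nodes]
    if len(ids) != len(set(ids)):
        # two complex expressions for the same target collide on node ids;
        # suffix later occurrences, keeping intra-expression references intact
        merged = _disambiguate_node_ids(merged)
    return merged


def _in_quotes_hash(line: str) -> bool:
    """True when a '#' appears inside a quoted literal (keep the line intact)."""
    h = line.find("#")
    return h >= 0 and line[:h].count('"') % 2 == 1


def _disambiguate_node_ids(graph: MappingGraph) -> MappingGraph:
    seen: dict[str, int] = {}
    rename: dict[int, str] = {}
    new_ids = []
    for idx, n in enumerate(graph.nodes):
        count = seen.get(n.id, 0)
        seen[n.id] = count + 1
        new_ids.append(n.id if count == 0 else f"{n.id}_v{count + 1}")
    # NodeRefs are only intra-expression, and within one expression ids are
    # unique, so refs rename consistently per expression occurrence order.
    mapping_per_occurrence: dict[str, list] = {}
    for old, new in zip((n.id for n in graph.nodes), new_ids):
        mapping_per_occurrence.setdefault(old, []).append(new)
    used: dict[str, int] = {}
    out_nodes = []
    for n, new_id in zip(graph.nodes, new_ids):
        def fix(op: Operand) -> Operand:
            if isinstance(op, NodeRef) and op.node_id in mapping_per_occurrence:
                variants = mapping_per_occurrence[op.node_id]
                # refer to the variant from the same expression block: the
                # one sharing this node's suffix
                suffix = new_id[len(n.id):] if new_id.startswith(n.id) else ""
                candidate = op.node_id + suffix
                return NodeRef(candidate if candidate in new_ids else variants[0])
            return op
        out_nodes.append(replace(n, id=new_id, operand1=fix(n.operand1), operand2=fix(n.operand2)))
    return MappingGraph(simple_mappings=list(graph.simple_mappings), nodes=out_nodes)


def unparse_mapping(graph: MappingGraph,
                    name_of: Callable[[str], str] = local_name) -> str:
    """Serialize a mapping graph back to prefix notation (one line per mapping)."""
    by_id = graph.node_by_id()
    consumed = {op.node_id for n in graph.nodes for op in n.operands
                if isinstance(op, NodeRef)}

    def render(op: Operand) -> str:
        if isinstance(op, Constant):
            escaped = op.value.replace("\\", "\\\\").replace('"', '\\"')
            return f'"{escaped}"'
        if isinstance(op, ConceptRef):
            return name_of(op.iri)
        return render_node(by_id[op.node_id])

    def render_node(n: MappingNode) -> str:
        return f"({n.command} {render(n.operand1)} {render(n.operand2)})"

    lines = [f"{name_of(t)}: {name_of(s)}" for t, s in graph.simple_mappings]
    for n in graph.nodes:
        if n.output_concept is not None or n.id not in consumed:
            target = name_of(n.output_concept) if n.output_concept else n.id
            lines.append(f"{target}: {render_node(n)}")
    return "\n".join(lines) + ("\n" if lines else "")
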