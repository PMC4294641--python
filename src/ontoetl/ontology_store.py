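"""Load, save, validate and query the RDF ontologies.

A thin, deterministic wrapper around :class:`rdflib.Graph`.  Triples are
the unit of knowledge everywhere in this package: every query returns
plain ``(subject, predicate, object)`` tuples in a stable sorted order so
that downstream SQL generation is byte-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDFS

from . import vocab
from .errors import OntologyError

#: serialization name -> rdflib format string
_FORMATS = {"turtle": "turtle", "rdf-xml": "xml"}
_SUFFIX_FORMATS = {".ttl": "turtle", ".owl": "rdf-xml", ".rdf": "rdf-xml", ".xml": "rdf-xml"}


def _rdflib_format(fmt: str) -> str:
    try:
        return _FORMATS[fmt]
    except KeyError:
        raise OntologyError(
            f"unknown serialization {fmt!r}; supported: {sorted(_FORMATS)}"
        ) from None


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    try:
        return _SUFFIX_FORMATS[path.suffix.lower()]
    except KeyError:
        raise OntologyError(
            f"cannot infer serialization from suffix of {path}; pass format="
        ) from None


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found by :meth:`OntologyGraph.validate_vocabulary`."""

    concept: str
    kind: str  # "unknown-predicate" | "arity" | "binding" | "literal-type"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.concept}: {self.message}"


class OntologyGraph:
    """A set of RDF triples with the package's vocabulary bound.

    Equality and round-trip guarantees are defined on the *set of triples*,
    independent of serialization order.
    """

    def __init__(self, graph: Optional[Graph] = None):
        self.graph = graph if graph is not None else Graph()
        self.graph.bind(vocab.PREFIX, vocab.OE, replace=True)

    # -- construction --------------------------------------------------------
    @classmethod
    def load(cls, path, format: Optional[str] = None) -> "OntologyGraph":
        """Parse a Turtle (``.ttl``) or RDF/XML (``.owl``/``.rdf``) file."""
        path = Path(path)
        fmt = _infer_format(path, format)
        g = Graph()
        try:
            g.parse(path, format=_rdflib_format(fmt))
        except FileNotFoundError:
            raise OntologyError(f"ontology file not found: {path}") from None
        except Exception as exc:  # rdflib raises serializer-specific classes
            raise OntologyError(f"cannot parse {path} as {fmt}: {exc}") from exc
        return cls(g)

    def save(self, path, format: Optional[str] = None) -> None:
        path = Path(path)
        fmt = _infer_format(path, format)
        try:
            self.graph.serialize(destination=path, format=_rdflib_format(fmt))
        except OSError as exc:
            raise OntologyError(f"cannot write {path}: {exc}") from exc

    # -- basic access ---------------------------------------------------------
    def add(self, triple) -> "OntologyGraph":
        self.graph.add(triple)
        return self

    def __len__(self) -> int:
        return len(self.graph)

    def __iter__(self) -> Iterator:
        return iter(self.graph)

    def triple_set(self) -> frozenset:
        return frozenset(self.graph)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return self.triple_set() == other.triple_set()

    def __hash__(self):  # pragma: no cover
        return hash(self.triple_set())

    # -- querying -------------------------------------------------------------
    def query_pattern(self, subject=None, predicate=None, obj=None) -> list:
        """All triples matching a pattern; ``None`` is a wildcard.

        The result is sorted by the N3 representation of its terms so that
        repeated runs (and SQL generated from them) are identical.
        """
        matches = self.graph.triples((subject, predicate, obj))
        return sorted(matches, key=lambda t: tuple(term.n3() for term in t))

    def value(self, subject, predicate):
        """Single object of ``(subject, predicate, ·)`` or None (sorted-first on ties)."""
        objs = self.query_pattern(subject, predicate, None)
        return objs[0][2] if objs else None

    def literal(self, subject, predicate) -> Optional[str]:
        """Single *literal* object as text, ignoring resource objects."""
        for _, _, o in self.query_pattern(subject, predicate, None):
            if isinstance(o, Literal):
                return str(o)
        return None

    def ancestors(self, concept: URIRef) -> list:
        """Concept followed by its ``rdfs:subClassOf`` ancestors, nearest first."""
        seen = [concept]
        frontier = concept
        while True:
            parent = self.value(frontier, RDFS.subClassOf)
            if parent is None or parent in seen:
                return seen
            seen.append(parent)
            frontier = parent

    def inherited_value(self, concept: URIRef, predicate):
        """Value of ``predicate`` on the concept or its nearest ancestor."""
        for node in self.ancestors(concept):
            v = self.value(node, predicate)
            if v is not None:
                return v
        return None

    # -- validation -----------------------------------------------------------
    def validate_vocabulary(self, role: Optional[str] = None) -> list:
        """Structural lint of the graph; issues are data, not exceptions.

        ``role`` narrows the checks: ``"source"`` additionally requires every
        filtered data element to reach a table binding, ``"mapping"``
        requires every mapping node to have exactly two operands.
        """
        issues: list[ValidationIssue] = []
        oe_ns = str(vocab.OE)

        predicates = {p for _, p, _ in self.graph}
        for p in sorted(predicates, key=str):
            if str(p).startswith(oe_ns) and p not in vocab.RECOGNIZED_PREDICATES:
                issues.append(
                    ValidationIssue(str(p), "unknown-predicate",
                                    "predicate is in the tool namespace but not recognized")
                )

        # Mapping-node arity: exactly one hasOperand1 and one hasOperand2.
        nodes = {s for s, _, _ in self.graph.triples((None, vocab.HAS_COMMAND_TYPE, None))}
        if role in (None, "mapping"):
            for node in sorted(nodes, key=str):
                for pred, name in ((vocab.HAS_OPERAND1, "operand 1"),
                                   (vocab.HAS_OPERAND2, "operand 2")):
                    n = len(list(self.graph.triples((node, pred, None))))
                    if n != 1:
                        issues.append(
                            ValidationIssue(str(node), "arity",
                                            f"mapping node has {n} {name} edges; exactly one required")
                        )

        if role == "source":
            elements = {s for s, _, _ in self.graph.triples((None, vocab.HAS_SELECT_FILTER, None))
                        if isinstance(s, URIRef)}
            # Command types also carry select filters; exclude them.
            elements -= {s for s, _, _ in self.graph.triples((None, vocab.HAS_OUTPUT_TRANSFORMATION, None))}
            for concept in sorted(elements, key=str):
                if self.inherited_value(concept, vocab.HAS_SOURCE_TABLE) is None:
                    issues.append(
                        ValidationIssue(str(concept), "binding",
                                        "no hasSourceTable on the concept or any ancestor")
                    )
        return issues


def brute_force_match(triples: Iterable, subject=None, predicate=None, obj=None) -> list:
    """Reference implementation of pattern matching: linear scan.

    Used by tests as the independent oracle for
    :meth:`OntologyGraph.query_pattern`.
    """
    out = [
        (s, p, o)
        for (s, p, o) in triples
        if (subject is None or s == subject)
        and (predicate is None or p == predicate)
        and (obj is None or o == obj)
    ]
    return sorted(out, key=lambda t: tuple(term.n3() for term in t))
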