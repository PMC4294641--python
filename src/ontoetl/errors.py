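"""Exception hierarchy.

Validation problems are reported as data (issue lists) wherever the caller
can reasonably continue; exceptions are reserved for states the pipeline
cannot proceed from (unparseable input, unresolvable bindings, SQL failure).
"""


class OntoETLError(Exception):
    """Base class for all errors raised by this package."""


class OntologyError(OntoETLError):
    """An ontology file could not be parsed or written."""


class BindingError(OntoETLError):
    """A source concept has no resolvable database binding."""


class MappingError(OntoETLError):
    """A mapping network is structurally invalid."""


class ExpressionParseError(MappingError):
    """A mapping expression in prefix notation is malformed.

    Carries the 1-based line and column of the offending token.
    """

    def __init__(self, message: str, line: int = 1, column: int = 0):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class UnknownConceptError(MappingError):
    """A concept name in a mapping expression matches no loaded concept."""


class SchedulingError(MappingError):
    """The operand dependency relation contains a cycle."""

    def __init__(self, cycle_nodes):
        self.cycle_nodes = list(cycle_nodes)
        super().__init__(
            "mapping nodes form a dependency cycle: " + ", ".join(map(str, self.cycle_nodes))
        )


class GenerationError(OntoETLError):
    """SQL generation failed (unresolved placeholder, missing upstream table)."""


class ExecutionError(OntoETLError):
    """Executing a generated SQL statement failed."""

    def __init__(self, node_id, statement, cause):
        self.node_id = node_id
        self.statement = statement
        self.cause = cause
        super().__init__(f"SQL execution failed at node {node_id}: {cause}")


class EvaluationError(OntoETLError):
    """The in-memory evaluator hit an undefined operation (strict mode)."""


class MetadataError(OntoETLError):
    """Target metadata could not be derived (e.g. colliding concept paths)."""
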