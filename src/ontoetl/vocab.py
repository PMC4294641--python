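"""The RDF vocabulary of the ETL ontologies.

All declarative ETL knowledge lives in plain RDF triples.  Three kinds of
graphs share one vocabulary namespace:

* the *source ontology* — an inventory of the source system's data elements
  together with their database bindings (table, columns, select filters),
* the *target ontology* — the research dataset's concepts with the metadata
  needed by an i2b2-like platform (path, code, datatype, unit),
* the *mapping ontology* — ``hasImport`` links for simple one-to-one
  mappings and intermediate two-operand nodes for complex transformations.

Concepts are modelled as plain resources; the class/instance distinction is
deliberately collapsed, which does not affect the semantics of any
operation in this package.
"""
from __future__ import annotations

from rdflib import Namespace
from rdflib.namespace import RDF, RDFS

#: Namespace of the tool's own vocabulary.  Fixed; user extensions must use
#: their own namespace.
OE = Namespace("https://ontoetl.dev/vocab#")

#: Conventional prefix bound on every graph this package writes.
PREFIX = "oe"

# --- database binding properties (source ontology) -------------------------
HAS_SOURCE_TABLE = OE.hasSourceTable            # concept -> table resource
HAS_SOURCE_TABLE_NAME = OE.hasSourceTableName   # table -> literal
HAS_DB_CONNECTION = OE.hasDBConnection          # table -> connection resource
HAS_CONNECTION_URL = OE.hasConnectionURL        # connection -> literal
HAS_ACCESS_SQL = OE.hasAccessSQL                # table -> SQL template literal
HAS_SELECT_FILTER = OE.hasSelectFilter          # concept/command -> SQL fragment

# Column mapping properties.  With a *literal* object they name a database
# column; with a *resource* object they overload the internal-data-model
# column with the Value of another concept's records (same document).
HAS_DOCUMENT_ID_COLUMN = OE.hasDocumentIDColumn
HAS_PATIENT_ID_COLUMN = OE.hasPatientIDColumn
HAS_CASE_ID_COLUMN = OE.hasCaseIDColumn
HAS_DATE_COLUMN = OE.hasDateColumn
HAS_DATE_START_VALUE_COLUMN = OE.hasDateStartValueColumn
HAS_DATE_END_VALUE_COLUMN = OE.hasDateEndValueColumn
HAS_VALUE_COLUMN = OE.hasValueColumn

# --- mapping ontology properties -------------------------------------------
HAS_IMPORT = OE.hasImport                       # target -> source / node
HAS_OPERAND1 = OE.hasOperand1
HAS_OPERAND2 = OE.hasOperand2
HAS_COMMAND_TYPE = OE.hasCommandType            # node -> command resource
HAS_CONSTANT_VALUE = OE.hasConstantValue        # constant operand -> literal

# --- command-type definition properties (Fig-5-style system ontology) -------
HAS_OUTPUT_TRANSFORMATION = OE.hasOutputTransformation
HAS_DATE_VALUE = OE.hasDateValue                # literal "OP1" | "OP2"
HAS_JOIN_KIND = OE.hasJoinKind                  # literal "inner"|"outer"|"op2_left"
HAS_NEUTRAL_ELEMENT = OE.hasNeutralElement
HAS_CATEGORY = OE.hasCategory

# --- target ontology metadata properties ------------------------------------
HAS_CONCEPT_CODE = OE.hasConceptCode
HAS_DATA_TYPE = OE.hasDataType                  # literal "text"|"numeric"|"date"
HAS_UNIT = OE.hasUnit
HAS_DESCRIPTION = OE.hasDescription

# --- source ontology value inventory ----------------------------------------
HAS_PERMISSIBLE_VALUE = OE.hasPermissibleValue  # element -> value resource
HAS_VALUE_CODE = OE.hasValueCode                # value resource -> literal

#: Column-mapping predicates in internal-data-model order (Value excluded:
#: it cannot be overloaded).
OVERLOADABLE_COLUMNS = {
    HAS_DOCUMENT_ID_COLUMN: "document_id",
    HAS_PATIENT_ID_COLUMN: "patient_id",
    HAS_CASE_ID_COLUMN: "case_id",
    HAS_DATE_START_VALUE_COLUMN: "date_start",
    HAS_DATE_END_VALUE_COLUMN: "date_end",
}

#: Every predicate this package recognises in its own namespace.
RECOGNIZED_PREDICATES = frozenset(
    {
        HAS_SOURCE_TABLE,
        HAS_SOURCE_TABLE_NAME,
        HAS_DB_CONNECTION,
        HAS_CONNECTION_URL,
        HAS_ACCESS_SQL,
        HAS_SELECT_FILTER,
        HAS_DOCUMENT_ID_COLUMN,
        HAS_PATIENT_ID_COLUMN,
        HAS_CASE_ID_COLUMN,
        HAS_DATE_COLUMN,
        HAS_DATE_START_VALUE_COLUMN,
        HAS_DATE_END_VALUE_COLUMN,
        HAS_VALUE_COLUMN,
        HAS_IMPORT,
        HAS_OPERAND1,
        HAS_OPERAND2,
        HAS_COMMAND_TYPE,
        HAS_CONSTANT_VALUE,
        HAS_OUTPUT_TRANSFORMATION,
        HAS_DATE_VALUE,
        HAS_JOIN_KIND,
        HAS_NEUTRAL_ELEMENT,
        HAS_CATEGORY,
        HAS_CONCEPT_CODE,
        HAS_DATA_TYPE,
        HAS_UNIT,
        HAS_DESCRIPTION,
        HAS_PERMISSIBLE_VALUE,
        HAS_VALUE_CODE,
    }
)

#: Predicates from the standard RDF/RDFS vocabularies that may appear in
#: any of the three ontologies (typing, labelling, hierarchy).
STANDARD_PREDICATES = frozenset({RDF.type, RDFS.label, RDFS.subClassOf, RDFS.comment})


def local_name(iri) -> str:
    """Last path/fragment segment of an IRI — the human-facing short name."""
    s = str(iri)
    for sep in ("#", "/", ":"):
        if sep in s:
            s = s.rsplit(sep, 1)[1]
    return s
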