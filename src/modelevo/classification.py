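"""COMODI-style annotation of diff operations.

Every operation gets exactly one Change term (from its operation type),
exactly one XmlEntity term (from the kind of XML node it touches), and a
set of Target terms derived purely from the operation's path context —
no intention or reason inference is attempted.

The Target vocabulary is a fixed lookup table from recognized container
element local-names to terms; unrecognized containers contribute nothing
rather than a guess.  Term IRIs live in a small mapping that can be
overridden from a YAML file so the ontology binding can track revisions
without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
import yaml

from .diff_engine import Delta, DiffOp
from .model_io import ModelDocument, XmlNode, local_name

__all__ = [
    "ComodiAnnotation",
    "ClassificationError",
    "classify_op",
    "classify_delta",
    "summarize_comodi",
    "CHANGE_TERMS",
    "XML_ENTITY_TERMS",
    "TARGET_BY_CONTAINER",
    "load_term_iris",
]

CHANGE_TERMS = {
    "insert": "Insertion",
    "delete": "Deletion",
    "update": "Update",
    "move": "Move",
}

XML_ENTITY_TERMS = {
    "element": "Node",
    "attribute": "Attribute",
    "text": "Text",
}

#: container local-name -> Target term.  Documented superset choice: the
#: table lists every container we recognize; anything else maps to the
#: empty set.
TARGET_BY_CONTAINER = {
    # SBML
    "listOfSpecies": "SpeciesSetup",
    "species": "SpeciesSetup",
    "specie": "SpeciesSetup",
    "listOfReactions": "ReactionDefinition",
    "reaction": "ReactionDefinition",
    "kineticLaw": "ReactionDefinition",
    "listOfCompartments": "CompartmentDefinition",
    "compartment": "CompartmentDefinition",
    "listOfParameters": "ParameterSetup",
    "parameter": "ParameterSetup",
    "localParameter": "ParameterSetup",
    "listOfFunctionDefinitions": "FunctionDefinition",
    "functionDefinition": "FunctionDefinition",
    "listOfRules": "RuleDefinition",
    "algebraicRule": "RuleDefinition",
    "assignmentRule": "RuleDefinition",
    "rateRule": "RuleDefinition",
    "listOfEvents": "EventDefinition",
    "event": "EventDefinition",
    "listOfUnitDefinitions": "UnitDefinition",
    "unitDefinition": "UnitDefinition",
    "unit": "UnitDefinition",
    # shared
    "annotation": "ModelAnnotation",
    "notes": "TextualDescription",
    "documentation": "TextualDescription",
    "math": "MathematicalModel",
    # CellML
    "component": "Component",
    "variable": "VariableSetup",
    "connection": "VariableConnection",
    "map_components": "VariableConnection",
    "map_variables": "VariableConnection",
    "units": "UnitDefinition",
}

TARGET_TERMS = tuple(sorted(set(TARGET_BY_CONTAINER.values())))

_COMODI_NS = "http://purl.uni-rostock.de/comodi/comodi#"

DEFAULT_TERM_IRIS = {
    term: _COMODI_NS + term
    for term in (
        list(CHANGE_TERMS.values()) + list(XML_ENTITY_TERMS.values()) + list(TARGET_TERMS)
    )
}


def load_term_iris(path: Optional[str] = None) -> dict[str, str]:
    """IRI map for all terms, optionally overridden from a YAML file."""
    iris = dict(DEFAULT_TERM_IRIS)
    if path:
        with open(path, "r", encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
        iris.update({str(k): str(v) for k, v in override.items()})
    return iris


class ClassificationError(ValueError):
    """The operation's anchor path does not resolve in the given document."""


@dataclass(frozen=True)
class ComodiAnnotation:
    change_term: str
    xml_entity_term: str
    target_terms: frozenset = field(default_factory=frozenset)


def _path_local_names(path: str) -> list[str]:
    names = []
    for seg in path.strip("/").split("/"):
        if seg.startswith("@"):
            names.append(seg[1:])
        elif seg.startswith("text()"):
            continue
        else:
            names.append(seg.partition("[")[0])
    return names


def _path_resolves(root: XmlNode, path: str) -> bool:
    segs = path.strip("/").split("/")
    node = root
    if not segs or segs[0] != f"{local_name(root.label)}[1]":
        return False
    for seg in segs[1:]:
        if seg.startswith("@"):
            return node.attr(seg[1:]) is not None
        if seg.startswith("text()["):
            i = int(seg[len("text()["):-1])
            return i <= len(node.text_children())
        name, _, idx = seg.partition("[")
        i = int(idx[:-1])
        found = [c for c in node.element_children() if local_name(c.label) == name]
        if i > len(found):
            return False
        node = found[i - 1]
    return True


def classify_op(op: DiffOp, doc_context: ModelDocument) -> ComodiAnnotation:
    """Annotate one operation; pure function of (op, path context).

    ``doc_context`` is the document in which the op's anchor path lives:
    the old version for deletes/updates, the new version for inserts.
    """
    anchor = op.new_path if op.op_type == "insert" else op.old_path
    if anchor is None:
        raise ClassificationError(f"operation has no anchor path: {op}")
    if not _path_resolves(doc_context.root, anchor):
        raise ClassificationError(f"path does not resolve in context: {anchor}")
    targets = frozenset(
        TARGET_BY_CONTAINER[n]
        for n in _path_local_names(anchor)
        if n in TARGET_BY_CONTAINER
    )
    return ComodiAnnotation(
        change_term=CHANGE_TERMS[op.op_type],
        xml_entity_term=XML_ENTITY_TERMS[op.entity_kind],
        target_terms=targets,
    )


def classify_delta(
    delta: Delta, doc_a: ModelDocument, doc_b: ModelDocument
) -> list[ComodiAnnotation]:
    """Annotate every operation of a delta (old-doc or new-doc context)."""
    return [
        classify_op(op, doc_b if op.op_type == "insert" else doc_a)
        for op in delta.ops
    ]


def summarize_comodi(
    annotated: Iterable[ComodiAnnotation] | Iterable[list[ComodiAnnotation]],
) -> pd.DataFrame:
    """Term-frequency table over all annotations, all terms listed.

    Accepts a flat iterable of annotations or an iterable of per-delta
    lists.  Returns a DataFrame with columns (branch, term, count), every
    known term present (zero counts included), deterministic row order.
    """
    flat: list[ComodiAnnotation] = []
    for item in annotated:
        if isinstance(item, ComodiAnnotation):
            flat.append(item)
        else:
            flat.extend(item)
    counts: dict[tuple[str, str], int] = {}
    for term in CHANGE_TERMS.values():
        counts[("Change", term)] = 0
    for term in XML_ENTITY_TERMS.values():
        counts[("XmlEntity", term)] = 0
    for term in TARGET_TERMS:
        counts[("Target", term)] = 0
    for ann in flat:
        counts[("Change", ann.change_term)] += 1
        counts[("XmlEntity", ann.xml_entity_term)] += 1
        for t in ann.target_terms:
            counts[("Target", t)] += 1
    rows = [
        {"branch": b, "term": t, "count": n}
        for (b, t), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["branch", "term", "count"])
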