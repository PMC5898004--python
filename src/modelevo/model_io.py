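"""Parsing, canonicalization and entity counting for SBML/CellML documents.

The module turns raw XML bytes into a canonicalized :class:`XmlNode` tree
wrapped in a :class:`ModelDocument`, provides a deterministic serializer
(``canonical_serialize``) under which cosmetic differences vanish, and
computes the per-version :class:`EntityCounts` feature vector.

Canonical form
--------------
* UTF-8 text, one XML declaration line.
* Attributes sorted lexicographically by (namespaced) name.
* Namespace prefixes rewritten to a stable table (``ns0``, ``ns1``, ... in
  lexicographic URI order; the root element's namespace is additionally
  declared as the default namespace and its elements are written
  unprefixed).
* Inter-element whitespace dropped; other text stripped of leading and
  trailing whitespace.
* Text inside ``notes`` / ``annotation`` / ``documentation`` subtrees is
  preserved verbatim and those subtrees are serialized inline without
  added indentation, so human-readable content round-trips byte-exactly.
* Comments and processing instructions are dropped.

"XML nodes" in :class:`EntityCounts` counts *element* nodes only;
attributes and text are excluded.  This makes the count comparable across
encoding formats but means absolute node totals are not comparable with
tools that count every DOM node.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterator, Optional
from xml.sax.saxutils import escape

__all__ = [
    "XmlNode",
    "ModelDocument",
    "EntityCounts",
    "ModelParseError",
    "UnsupportedFormatError",
    "parse_model",
    "count_entities",
    "canonical_serialize",
    "canonical_equal",
    "finalize_tree",
    "local_name",
    "namespace_uri",
    "iter_elements",
]

#: subtrees whose text content is semantically meaningful and kept verbatim
PRESERVE_TEXT_LOCALNAMES = frozenset({"notes", "annotation", "documentation"})

CELLML_NS_PREFIX = "http://www.cellml.org/cellml/"
SBML_NS_PREFIX = "http://www.sbml.org/sbml/"


class ModelParseError(ValueError):
    """Raised for malformed XML; the message names the line/column offset."""


class UnsupportedFormatError(ValueError):
    """Raised when the root element is neither SBML nor CellML."""


def local_name(label: str) -> str:
    """Local part of a Clark-notation name (``{uri}local`` -> ``local``)."""
    return label.rsplit("}", 1)[-1]


def namespace_uri(label: str) -> str:
    """Namespace URI of a Clark-notation name ('' when unqualified)."""
    if label.startswith("{"):
        return label[1:].split("}", 1)[0]
    return ""


@dataclass(eq=False)
class XmlNode:
    """One node of a canonicalized document tree.

    Node identity is object identity (``eq=False``): two structurally
    equal siblings must remain distinguishable inside children lists.

    ``kind`` is one of ``element``, ``attribute``, ``text``.  Element
    nodes carry ordered content ``children`` (elements and text nodes)
    and a separate list of ``attributes`` sorted by label; attribute and
    text nodes carry a ``value`` and never have children.  ``path`` is a
    slash-separated address from the root with 1-based indices among
    siblings sharing the same local name (XPath-like), unique per tree.
    """

    kind: str
    label: str
    value: Optional[str] = None
    children: list["XmlNode"] = field(default_factory=list)
    attributes: list["XmlNode"] = field(default_factory=list)
    path: str = ""

    # -- convenience -------------------------------------------------
    def attr(self, name: str) -> Optional[str]:
        for a in self.attributes:
            if a.label == name:
                return a.value
        return None

    def set_attr(self, name: str, value: str) -> None:
        for a in self.attributes:
            if a.label == name:
                a.value = value
                return
        self.attributes.append(XmlNode(kind="attribute", label=name, value=value))
        self.attributes.sort(key=lambda a: a.label)

    def remove_attr(self, name: str) -> None:
        self.attributes = [a for a in self.attributes if a.label != name]

    def element_children(self) -> list["XmlNode"]:
        return [c for c in self.children if c.kind == "element"]

    def text_children(self) -> list["XmlNode"]:
        return [c for c in self.children if c.kind == "text"]


@dataclass
class ModelDocument:
    """A parsed, canonicalized model version."""

    format: str  # "SBML" | "CellML"
    model_id: str
    version_id: str
    timestamp: datetime
    root: XmlNode
    source_uri: str = ""


@dataclass
class EntityCounts:
    """Per-version feature vector: element-node total plus ten entity counts."""

    nodes: int = 0
    species: int = 0
    reactions: int = 0
    compartments: int = 0
    functions: int = 0
    parameters: int = 0
    rules: int = 0
    events: int = 0
    units: int = 0
    variables: int = 0
    components: int = 0
    curation_status: str = "unknown"
    format: str = ""
    model_id: str = ""
    version_id: str = ""
    file_url: str = ""

    COUNT_FIELDS = (
        "nodes",
        "species",
        "reactions",
        "compartments",
        "functions",
        "parameters",
        "rules",
        "events",
        "units",
        "variables",
        "components",
    )

    def as_dict(self) -> dict:
        return {
            **{f: getattr(self, f) for f in self.COUNT_FIELDS},
            "curation_status": self.curation_status,
            "format": self.format,
            "model_id": self.model_id,
            "version_id": self.version_id,
            "file_url": self.file_url,
        }


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------

def _convert(elem: ET.Element, preserve: bool) -> XmlNode:
    label = elem.tag
    preserve_here = preserve or local_name(label) in PRESERVE_TEXT_LOCALNAMES
    node = XmlNode(kind="element", label=label)
    node.attributes = [
        XmlNode(kind="attribute", label=k, value=v)
        for k, v in sorted(elem.attrib.items())
    ]
    children: list[XmlNode] = []

    def add_text(t: Optional[str]) -> None:
        if not t:
            return
        if preserve_here:
            children.append(XmlNode(kind="text", label="#text", value=t))
        else:
            s = t.strip()
            if s:
                children.append(XmlNode(kind="text", label="#text", value=s))

    add_text(elem.text)
    for ch in elem:
        children.append(_convert(ch, preserve_here))
        add_text(ch.tail)
    node.children = children
    return node


def assign_paths(root: XmlNode) -> None:
    """(Re)compute the canonical path of every node in the tree."""
    root.path = f"/{local_name(root.label)}[1]"
    _assign_paths_below(root)


def _assign_paths_below(node: XmlNode) -> None:
    for a in node.attributes:
        a.path = f"{node.path}/@{a.label}"
    counters: dict[str, int] = {}
    text_i = 0
    for c in node.children:
        if c.kind == "element":
            name = local_name(c.label)
            counters[name] = counters.get(name, 0) + 1
            c.path = f"{node.path}/{name}[{counters[name]}]"
            _assign_paths_below(c)
        else:
            text_i += 1
            c.path = f"{node.path}/text()[{text_i}]"


def finalize_tree(root: XmlNode) -> XmlNode:
    """Sort attributes and assign paths; returns the root for chaining."""
    for el in iter_elements(root):
        el.attributes.sort(key=lambda a: a.label)
    assign_paths(root)
    return root


def iter_elements(root: XmlNode) -> Iterator[XmlNode]:
    """Pre-order iteration over element nodes."""
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.element_children()))


def iter_nodes(root: XmlNode) -> Iterator[XmlNode]:
    """Pre-order iteration over all nodes (elements, attributes, text)."""
    for el in iter_elements(root):
        yield el
        yield from el.attributes
        for c in el.children:
            if c.kind == "text":
                yield c


def _detect_format(root: XmlNode) -> str:
    name = local_name(root.label)
    ns = namespace_uri(root.label)
    if name == "sbml":
        return "SBML"
    if name == "model" and ns.startswith(CELLML_NS_PREFIX):
        return "CellML"
    raise UnsupportedFormatError(
        f"root element <{name}> (namespace {ns!r}) is neither SBML nor CellML"
    )


def parse_model(
    raw: bytes | str,
    model_id: str = "",
    version_id: str = "",
    timestamp: Optional[datetime] = None,
    source_uri: str = "",
) -> ModelDocument:
    """Parse raw XML into a canonicalized :class:`ModelDocument`.

    Raises :class:`ModelParseError` on malformed XML (the message carries
    the parser's position) and :class:`UnsupportedFormatError` when the
    root element is neither ``sbml`` nor a CellML ``model``.
    """
    if isinstance(raw, str):
        raw = raw.encode("utf-8")
    try:
        etree_root = ET.fromstring(raw)
    except ET.ParseError as exc:  # position is (line, column)
        raise ModelParseError(f"malformed XML: {exc}") from exc
    root = _convert(etree_root, preserve=False)
    fmt = _detect_format(root)
    finalize_tree(root)
    if timestamp is None:
        timestamp = datetime(1970, 1, 1, tzinfo=timezone.utc)
    return ModelDocument(
        format=fmt,
        model_id=model_id,
        version_id=version_id,
        timestamp=timestamp,
        root=root,
        source_uri=source_uri,
    )


# ----------------------------------------------------------------------
# canonical serialization
# ----------------------------------------------------------------------

def _collect_namespaces(root: XmlNode) -> list[str]:
    uris = set()
    for n in iter_nodes(root):
        if n.kind in ("element", "attribute"):
            ns = namespace_uri(n.label)
            if ns:
                uris.add(ns)
    return sorted(uris)


def _attr_escape(v: str) -> str:
    return escape(v, {'"': "&quot;", "\n": "&#10;", "\t": "&#9;"})


class _Serializer:
    def __init__(self, root: XmlNode):
        self.uris = _collect_namespaces(root)
        self.prefix = {u: f"ns{i}" for i, u in enumerate(self.uris)}
        self.default_ns = namespace_uri(root.label)

    def tag(self, label: str) -> str:
        ns = namespace_uri(label)
        if not ns or ns == self.default_ns:
            return local_name(label)
        return f"{self.prefix[ns]}:{local_name(label)}"

    def attr_name(self, label: str) -> str:
        ns = namespace_uri(label)
        if not ns:
            return label
        return f"{self.prefix[ns]}:{local_name(label)}"

    def open_tag(self, node: XmlNode, declare_ns: bool) -> str:
        parts = [self.tag(node.label)]
        if declare_ns:
            if self.default_ns:
                parts.append(f'xmlns="{_attr_escape(self.default_ns)}"')
            for u in self.uris:
                parts.append(f'xmlns:{self.prefix[u]}="{_attr_escape(u)}"')
        for a in sorted(node.attributes, key=lambda a: a.label):
            parts.append(f'{self.attr_name(a.label)}="{_attr_escape(a.value or "")}"')
        return " ".join(parts)

    def inline(self, node: XmlNode, out: io.StringIO, declare_ns: bool = False) -> None:
        if not node.children:
            out.write(f"<{self.open_tag(node, declare_ns)}/>")
            return
        out.write(f"<{self.open_tag(node, declare_ns)}>")
        for c in node.children:
            if c.kind == "text":
                out.write(escape(c.value or ""))
            else:
                self.inline(c, out)
        out.write(f"</{self.tag(node.label)}>")

    def block(self, node: XmlNode, out: io.StringIO, depth: int) -> None:
        pad = "  " * depth
        declare = depth == 0
        if local_name(node.label) in PRESERVE_TEXT_LOCALNAMES:
            out.write(pad)
            self.inline(node, out, declare)
            out.write("\n")
            return
        if not node.children:
            out.write(f"{pad}<{self.open_tag(node, declare)}/>\n")
            return
        out.write(f"{pad}<{self.open_tag(node, declare)}>\n")
        for c in node.children:
            if c.kind == "text":
                out.write(f"{pad}  {escape(c.value or '')}\n")
            else:
                self.block(c, out, depth + 1)
        out.write(f"{pad}</{self.tag(node.label)}>\n")


def canonical_serialize(doc: ModelDocument | XmlNode) -> str:
    """Deterministic text form: byte-identical for semantically equal trees."""
    root = doc.root if isinstance(doc, ModelDocument) else doc
    out = io.StringIO()
    out.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    _Serializer(root).block(root, out, 0)
    return out.getvalue()


def canonical_equal(a: ModelDocument | XmlNode, b: ModelDocument | XmlNode) -> bool:
    return canonical_serialize(a) == canonical_serialize(b)


# ----------------------------------------------------------------------
# entity counting
# ----------------------------------------------------------------------

_SBML_ENTITY = {
    "species": "species",
    "specie": "species",  # SBML Level 1 dialect
    "reaction": "reactions",
    "compartment": "compartments",
    "functionDefinition": "functions",
    "parameter": "parameters",
    "localParameter": "parameters",
    "algebraicRule": "rules",
    "assignmentRule": "rules",
    "rateRule": "rules",
    "speciesConcentrationRule": "rules",
    "specieConcentrationRule": "rules",
    "compartmentVolumeRule": "rules",
    "parameterRule": "rules",
    "event": "events",
    "unitDefinition": "units",
}

_CELLML_ENTITY = {
    "variable": "variables",
    "component": "components",
    "units": "units",
}


def count_entities(
    doc: ModelDocument,
    curation_status: str = "unknown",
    file_url: str = "",
) -> EntityCounts:
    """Count element nodes and format-native model entities.

    Counts are format-native: SBML documents report zero variables and
    components, CellML documents report zero species/reactions/etc.
    """
    table = _SBML_ENTITY if doc.format == "SBML" else _CELLML_ENTITY
    counts = EntityCounts(
        curation_status=curation_status,
        format=doc.format,
        model_id=doc.model_id,
        version_id=doc.version_id,
        file_url=file_url or doc.source_uri,
    )
    for el in iter_elements(doc.root):
        counts.nodes += 1
        key = table.get(local_name(el.label))
        if key:
            setattr(counts, key, getattr(counts, key) + 1)
    return counts
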