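"""Deterministic generation of model corpora with planted edit scripts.

``generate_seed_model`` builds skeleton SBML or CellML documents of a
requested size; ``generate_history`` derives a chain of versions from a
seed by planting randomly sampled but *recorded* edits, returning a
:class:`GroundTruthLedger` whose operations are exactly what the diff
engine is expected to report.  ``write_corpus`` emits the on-disk
ingestion layout consumed by the statistics builders.

Planted edits are sampled so that recovery is well-defined:

* edits never overlap (an edited subtree is claimed and left alone);
* planted moves relocate id-bearing elements, either to a different
  parent or jumping over at least two stable siblings within the same
  parent (so the moved element — not a bystander — breaks the sibling
  order);
* freshly inserted elements carry distinctive attribute values so the
  similarity fallback cannot pair them with deleted residuals;
* with ``id_stability=True`` identity attributes are never touched, with
  ``id_stability=False`` updates may rename them.

All randomness flows from a single seed; regeneration is byte-exact.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional

from .diff_engine import DiffOp
from .model_io import (
    EntityCounts,
    ModelDocument,
    XmlNode,
    canonical_serialize,
    count_entities,
    finalize_tree,
    iter_elements,
    local_name,
)

__all__ = [
    "EditSpec",
    "GroundTruthLedger",
    "generate_seed_model",
    "generate_history",
    "write_corpus",
    "ops_multiset",
    "path_level_scores",
]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CELLML_NS = "http://www.cellml.org/cellml/1.0#"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
XHTML_NS = "http://www.w3.org/1999/xhtml"
ANNOT_NS = "http://example.org/meta"

EPOCH = datetime(2005, 4, 11, tzinfo=timezone.utc)

IDENTITY_ATTRIBUTES = ("id", "metaid", "name")


@dataclass
class EditSpec:
    """Parameters controlling one transition's planted edits."""

    n_edits: int = 5
    op_mix: dict = field(
        default_factory=lambda: {
            "insert": 0.30, "delete": 0.25, "update": 0.30, "move": 0.15
        }
    )
    entity_mix: dict = field(
        default_factory=lambda: {"element": 0.60, "attribute": 0.25, "text": 0.15}
    )
    id_stability: bool = True
    #: probability that an update targets notes/annotation text rather
    #: than a structural attribute
    notes_bias: float = 0.25
    #: probability that an update renames an identity attribute when
    #: id_stability is off
    rename_prob: float = 0.4

    def validate(self) -> None:
        if self.n_edits < 0:
            raise ValueError("n_edits must be >= 0")
        for mix in (self.op_mix, self.entity_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"probabilities must sum to 1: {mix}")


@dataclass
class GroundTruthLedger:
    """Planted ops per transition plus expected per-version count deltas."""

    model_id: str
    transitions: list[list[DiffOp]] = field(default_factory=list)
    count_deltas: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "transitions": [
                    [op.to_dict() for op in ops] for ops in self.transitions
                ],
                "count_deltas": self.count_deltas,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLedger":
        d = json.loads(text)
        return cls(
            model_id=d["model_id"],
            transitions=[
                [DiffOp.from_dict(o) for o in ops] for ops in d["transitions"]
            ],
            count_deltas=d["count_deltas"],
        )


# ----------------------------------------------------------------------
# seed documents
# ----------------------------------------------------------------------

def _el(label: str, attrs: Optional[dict] = None, children: Optional[list] = None) -> XmlNode:
    node = XmlNode(kind="element", label=label)
    if attrs:
        node.attributes = [
            XmlNode(kind="attribute", label=k, value=str(v))
            for k, v in attrs.items()
        ]
    if children:
        node.children = list(children)
    return node


def _text(value: str) -> XmlNode:
    return XmlNode(kind="text", label="#text", value=value)


def _q(ns: str, name: str) -> str:
    return f"{{{ns}}}{name}"


def _sbml_species(i: int, compartment: str, rng: random.Random) -> XmlNode:
    return _el(
        _q(SBML_NS, "species"),
        {
            "id": f"s{i}",
            "name": f"species {i}",
            "compartment": compartment,
            "initialConcentration": f"{rng.randint(1, 500) / 10.0}",
            "boundaryCondition": rng.choice(["true", "false"]),
            "hasOnlySubstanceUnits": "false",
        },
    )


def _sbml_reaction(
    i: int, species_ids: list[str], with_local_param: bool, rng: random.Random
) -> XmlNode:
    reactant = rng.choice(species_ids) if species_ids else "s0"
    product = rng.choice(species_ids) if species_ids else "s0"
    kinetic_children: list[XmlNode] = [
        _el(_q(MATHML_NS, "math"), None, [_text(f"k{i}*{reactant}")])
    ]
    if with_local_param:
        kinetic_children.append(
            _el(
                _q(SBML_NS, "listOfParameters"),
                None,
                [
                    _el(
                        _q(SBML_NS, "parameter"),
                        {
                            "id": f"k{i}",
                            "name": f"rate constant {i}",
                            "value": f"{rng.randint(1, 100) / 100.0}",
                            "constant": "true",
                        },
                    )
                ],
            )
        )
    return _el(
        _q(SBML_NS, "reaction"),
        {"id": f"r{i}", "name": f"reaction {i}", "reversible": rng.choice(["true", "false"])},
        [
            _el(
                _q(SBML_NS, "listOfReactants"),
                None,
                [_el(_q(SBML_NS, "speciesReference"), {"species": reactant, "stoichiometry": "1"})],
            ),
            _el(
                _q(SBML_NS, "listOfProducts"),
                None,
                [_el(_q(SBML_NS, "speciesReference"), {"species": product, "stoichiometry": "1"})],
            ),
            _el(_q(SBML_NS, "kineticLaw"), None, kinetic_children),
        ],
    )


def _sbml_seed(model_id: str, size: dict, rng: random.Random) -> XmlNode:
    n_species = size.get("species", 5)
    n_reactions = size.get("reactions", 3)
    n_compartments = size.get("compartments", 1)
    n_parameters = size.get("parameters", 3)
    n_units = size.get("units", 1)
    n_local = size.get("local_parameters", min(2, n_reactions))

    compartments = [
        _el(
            _q(SBML_NS, "compartment"),
            {
                "id": f"c{i}",
                "name": f"compartment {i}",
                "size": f"{rng.randint(1, 10)}",
                "spatialDimensions": "3",
                "constant": "true",
            },
        )
        for i in range(n_compartments)
    ]
    species_ids = [f"s{i}" for i in range(n_species)]
    species = [
        _sbml_species(i, f"c{rng.randrange(max(1, n_compartments))}", rng)
        for i in range(n_species)
    ]
    parameters = [
        _el(
            _q(SBML_NS, "parameter"),
            {
                "id": f"p{i}",
                "name": f"parameter {i}",
                "value": f"{rng.randint(1, 1000) / 10.0}",
                "units": "dimensionless",
                "constant": "true",
            },
        )
        for i in range(n_parameters)
    ]
    reactions = [
        _sbml_reaction(i, species_ids, i < n_local, rng) for i in range(n_reactions)
    ]
    unit_defs = [
        _el(
            _q(SBML_NS, "unitDefinition"),
            {"id": f"ud{i}", "name": f"unit {i}"},
            [
                _el(
                    _q(SBML_NS, "listOfUnits"),
                    None,
                    [_el(_q(SBML_NS, "unit"), {"kind": "mole", "scale": "-3"})],
                )
            ],
        )
        for i in range(n_units)
    ]
    model_children: list[XmlNode] = [
        _el(_q(SBML_NS, "notes"), None, [_el(_q(XHTML_NS, "p")), _text(f"Model {model_id} revision 0.")]),
        _el(
            _q(SBML_NS, "annotation"),
            None,
            [_el(_q(ANNOT_NS, "info"), {"source": "synthetic", "revision": "0"})],
        ),
    ]
    if n_units:
        model_children.append(_el(_q(SBML_NS, "listOfUnitDefinitions"), None, unit_defs))
    model_children.append(_el(_q(SBML_NS, "listOfCompartments"), None, compartments))
    model_children.append(_el(_q(SBML_NS, "listOfSpecies"), None, species))
    model_children.append(_el(_q(SBML_NS, "listOfParameters"), None, parameters))
    model_children.append(_el(_q(SBML_NS, "listOfReactions"), None, reactions))
    model = _el(_q(SBML_NS, "model"), {"id": model_id, "name": f"model {model_id}"}, model_children)
    return _el(_q(SBML_NS, "sbml"), {"level": "2", "version": "4"}, [model])


def _cellml_seed(model_id: str, size: dict, rng: random.Random) -> XmlNode:
    n_components = size.get("components", 3)
    n_variables = size.get("variables", 6)
    n_units = size.get("units", 1)
    n_connections = size.get("connections", max(0, n_components - 1))

    units = [
        _el(
            _q(CELLML_NS, "units"),
            {"name": f"unit{i}"},
            [_el(_q(CELLML_NS, "unit"), {"units": "second", "exponent": "1"})],
        )
        for i in range(n_units)
    ]
    components = []
    var_names: list[list[str]] = [[] for _ in range(max(1, n_components))]
    for v in range(n_variables):
        var_names[v % max(1, n_components)].append(f"v{v}")
    for i in range(n_components):
        variables = [
            _el(
                _q(CELLML_NS, "variable"),
                {
                    "name": name,
                    "units": "second",
                    "initial_value": f"{rng.randint(0, 100) / 10.0}",
                    "public_interface": rng.choice(["in", "out", "none"]),
                    "private_interface": "none",
                },
            )
            for name in var_names[i]
        ]
        components.append(_el(_q(CELLML_NS, "component"), {"name": f"comp{i}"}, variables))
    connections = []
    for i in range(n_connections):
        c1 = f"comp{i % max(1, n_components)}"
        c2 = f"comp{(i + 1) % max(1, n_components)}"
        connections.append(
            _el(
                _q(CELLML_NS, "connection"),
                None,
                [
                    _el(_q(CELLML_NS, "map_components"), {"component_1": c1, "component_2": c2}),
                    _el(_q(CELLML_NS, "map_variables"), {"variable_1": f"v{i}", "variable_2": f"v{i}"}),
                ],
            )
        )
    children: list[XmlNode] = [
        _el(
            _q(CELLML_NS, "documentation"),
            None,
            [_el(_q(XHTML_NS, "p")), _text(f"CellML model {model_id} revision 0.")],
        )
    ]
    children.extend(units)
    children.extend(components)
    children.extend(connections)
    return _el(_q(CELLML_NS, "model"), {"name": model_id}, children)


def generate_seed_model(
    format: str,
    size_params: Optional[dict] = None,
    rng_seed: int = 0,
    model_id: str = "M0000",
    timestamp: Optional[datetime] = None,
) -> ModelDocument:
    """Deterministically build a skeleton model of the requested size."""
    size = dict(size_params or {})
    for v in size.values():
        if v < 0:
            raise ValueError("size parameters must be non-negative")
    rng = random.Random(rng_seed)
    fmt = format.upper().replace("CELLML", "CellML")
    if fmt == "SBML":
        root = _sbml_seed(model_id, size, rng)
    elif fmt == "CellML":
        root = _cellml_seed(model_id, size, rng)
    else:
        raise ValueError(f"unknown format {format!r}")
    finalize_tree(root)
    return ModelDocument(
        format=fmt,
        model_id=model_id,
        version_id="v0",
        timestamp=timestamp or EPOCH,
        root=root,
        source_uri=f"synthetic://{model_id}/v0",
    )


# ----------------------------------------------------------------------
# planting edits
# ----------------------------------------------------------------------

def _copy_with_map(node: XmlNode, orig_of: dict[int, XmlNode]) -> XmlNode:
    c = XmlNode(kind=node.kind, label=node.label, value=node.value, path=node.path)
    c.attributes = [
        XmlNode(kind="attribute", label=a.label, value=a.value, path=a.path)
        for a in node.attributes
    ]
    c.children = [_copy_with_map(ch, orig_of) for ch in node.children]
    orig_of[id(c)] = node
    return c


def _subtree_ids(el: XmlNode) -> set[int]:
    out = set()
    for e in iter_elements(el):
        out.add(id(e))
        for c in e.children:
            if c.kind == "text":
                out.add(id(c))
    return out


def _identity_attr(el: XmlNode) -> Optional[str]:
    for a in IDENTITY_ATTRIBUTES:
        if el.attr(a) is not None:
            return a
    return None


class _Planter:
    """Applies one transition's edits to a working copy, recording them."""

    def __init__(self, doc: ModelDocument, spec: EditSpec, rng: random.Random,
                 fresh_counter: int):
        self.doc = doc
        self.spec = spec
        self.rng = rng
        self.orig_of: dict[int, XmlNode] = {}
        self.b_root = _copy_with_map(doc.root, self.orig_of)
        self.b_parent: dict[int, Optional[XmlNode]] = {id(self.b_root): None}
        for el in iter_elements(self.b_root):
            for c in el.children:
                self.b_parent[id(c)] = el
        self.claimed: set[int] = set()
        # A-side node ids touched by any edit; deleting an ancestor of a
        # touched node would double-record its subtree in the ledger
        self.a_claimed: set[int] = set()
        self.move_frozen: set[int] = set()        # containers with a planted move
        self.structure_touched: set[int] = set()  # containers with any child edit
        self.records: list[tuple] = []
        self.fresh = fresh_counter
        self.fmt = doc.format
        self.ns = SBML_NS if self.fmt == "SBML" else CELLML_NS
        self._recompute_safe()

    # -- bookkeeping -------------------------------------------------
    def _recompute_safe(self) -> None:
        """Elements whose match in the old version is guaranteed: id-bearing,
        or children of safe parents whose label is unique among siblings in
        BOTH versions (a sibling deleted or inserted this transition would
        otherwise make the survivor look unique while it is ambiguous for
        the matcher)."""
        self.safe: set[int] = set()

        def rec(el: XmlNode) -> None:
            self.safe.add(id(el))
            groups: dict[str, int] = {}
            for c in el.element_children():
                groups[c.label] = groups.get(c.label, 0) + 1
            orig = self.orig_of.get(id(el))
            a_groups: dict[str, int] = {}
            if orig is not None:
                for c in orig.element_children():
                    a_groups[c.label] = a_groups.get(c.label, 0) + 1
            for c in el.element_children():
                if id(c) in self.claimed or id(c) not in self.orig_of:
                    continue
                unique_both = groups[c.label] == 1 and a_groups.get(c.label) == 1
                if _identity_attr(c) is not None or unique_both:
                    rec(c)

        rec(self.b_root)

    def _claim_subtree(self, el: XmlNode) -> None:
        self.claimed |= _subtree_ids(el)

    def _free_subtree(self, el: XmlNode) -> bool:
        if any(i in self.claimed for i in _subtree_ids(el)):
            return False
        p = self.b_parent.get(id(el))
        while p is not None:
            if id(p) in self.claimed:
                return False
            p = self.b_parent.get(id(p))
        return True

    def _fresh_id(self, prefix: str) -> str:
        self.fresh += 1
        return f"{prefix}x{self.fresh}"

    def _elements(self) -> list[XmlNode]:
        return list(iter_elements(self.b_root))

    def _container_ok(self, container: XmlNode) -> bool:
        return id(container) not in self.move_frozen and self._free_subtree_shallow(container)

    def _free_subtree_shallow(self, el: XmlNode) -> bool:
        # the container itself and its ancestors must be unclaimed (children may be)
        n: Optional[XmlNode] = el
        while n is not None:
            if id(n) in self.claimed:
                return False
            n = self.b_parent.get(id(n))
        return True

    # -- edit attempts: each returns True when applied --------------
    def try_insert_element(self) -> bool:
        cands = []
        for el in self._elements():
            name = local_name(el.label)
            if not self._container_ok(el):
                continue
            if self.fmt == "SBML":
                if name in ("listOfSpecies", "listOfParameters", "listOfCompartments",
                            "listOfReactions"):
                    cands.append(el)
            else:
                if name == "component" or (name == "model" and id(el) == id(self.b_root)):
                    cands.append(el)
        if not cands:
            return False
        container = self.rng.choice(cands)
        name = local_name(container.label)
        rng = self.rng
        if self.fmt == "SBML":
            if name == "listOfSpecies":
                node = _el(_q(SBML_NS, "species"), {
                    "id": self._fresh_id("s"), "name": self._fresh_id("new species "),
                    "compartment": self._fresh_id("c"),
                    "initialConcentration": f"{rng.randint(501, 999)}",
                    "sboTerm": f"SBO:{rng.randint(1000000, 9999999)}",
                })
            elif name == "listOfParameters":
                node = _el(_q(SBML_NS, "parameter"), {
                    "id": self._fresh_id("p"), "name": self._fresh_id("new parameter "),
                    "value": f"{rng.randint(1001, 9999)}",
                    "units": self._fresh_id("u"),
                })
            elif name == "listOfCompartments":
                node = _el(_q(SBML_NS, "compartment"), {
                    "id": self._fresh_id("c"), "name": self._fresh_id("new compartment "),
                    "size": f"{rng.randint(11, 99)}",
                    "outside": self._fresh_id("c"),
                })
            else:
                rid = self._fresh_id("r")
                node = _el(_q(SBML_NS, "reaction"),
                           {"id": rid, "name": f"new reaction {rid}",
                            "reversible": "false"},
                           [_el(_q(SBML_NS, "listOfReactants"), None,
                                [_el(_q(SBML_NS, "speciesReference"),
                                     {"species": self._fresh_id("s"),
                                      "stoichiometry": f"{rng.randint(2, 9)}"})])])
        else:
            if name == "component":
                node = _el(_q(CELLML_NS, "variable"), {
                    "name": self._fresh_id("v"), "units": self._fresh_id("u"),
                    "initial_value": f"{rng.randint(1001, 9999)}",
                    "public_interface": "none",
                })
            else:
                cid = self._fresh_id("comp")
                node = _el(_q(CELLML_NS, "component"), {"name": cid},
                           [_el(_q(CELLML_NS, "variable"),
                                {"name": self._fresh_id("v"),
                                 "units": self._fresh_id("u")})])
        pos = self.rng.randrange(len(container.children) + 1)
        container.children.insert(pos, node)
        for e in iter_elements(node):
            self.b_parent[id(e)] = None  # placeholder; fixed below
        self._register_parents(node, container)
        self._claim_subtree(node)
        self.structure_touched.add(id(container))
        self.records.append(("ins_el", node))
        self._recompute_safe()
        return True

    def _register_parents(self, node: XmlNode, parent: XmlNode) -> None:
        self.b_parent[id(node)] = parent
        for el in iter_elements(node):
            for c in el.children:
                self.b_parent[id(c)] = el

    def try_delete_element(self) -> bool:
        deletable = {"species", "parameter", "reaction", "unitDefinition",
                     "compartment"} if self.fmt == "SBML" else {
                         "variable", "units", "component", "connection"}
        cands = []
        for el in self._elements():
            if id(el) not in self.orig_of:
                continue
            if local_name(el.label) not in deletable:
                continue
            parent = self.b_parent.get(id(el))
            if parent is None or id(parent) in self.move_frozen:
                continue
            if not self._free_subtree(el):
                continue
            if _subtree_ids(self.orig_of[id(el)]) & self.a_claimed:
                continue
            cands.append(el)
        if not cands:
            return False
        el = self.rng.choice(cands)
        parent = self.b_parent[id(el)]
        orig = self.orig_of[id(el)]
        self.records.append(("del_el", el, orig))
        self._claim_subtree(el)
        self.a_claimed |= _subtree_ids(orig)
        parent.children.remove(el)
        self.structure_touched.add(id(parent))
        self._recompute_safe()
        return True

    def _update_targets(self) -> list[XmlNode]:
        out = []
        for el in self._elements():
            if id(el) in self.claimed or id(el) not in self.orig_of:
                continue
            if id(el) not in self.safe:
                continue
            if not self._free_subtree_shallow(el):
                continue
            out.append(el)
        return out

    def try_update_attribute(self) -> bool:
        rename = (not self.spec.id_stability) and self.rng.random() < self.spec.rename_prob
        cands = []
        for el in self._update_targets():
            idattr = _identity_attr(el)
            for a in el.attributes:
                if rename:
                    if a.label == idattr:
                        cands.append((el, a))
                elif a.label != idattr:
                    cands.append((el, a))
        if not cands:
            return False
        el, a = self.rng.choice(cands)
        old = a.value
        new = self._fresh_id("val")
        a.value = new
        self.claimed.add(id(el))
        self.a_claimed.add(id(self.orig_of[id(el)]))
        self.records.append(("upd_attr", el, self.orig_of[id(el)], a.label, old, new))
        if rename:
            self._recompute_safe()
        return True

    def try_update_text(self) -> bool:
        cands = []
        for el in self._update_targets():
            for t in el.text_children():
                cands.append((el, t))
        if not cands:
            return False
        el, t = self.rng.choice(cands)
        old = t.value
        new = f"edited text {self._fresh_id('t')}"
        t.value = new
        self.claimed.add(id(el))
        self.a_claimed.add(id(self.orig_of[id(t)]))
        self.records.append(("upd_text", t, self.orig_of[id(t)], old, new))
        return True

    def try_insert_attribute(self) -> bool:
        fresh_attr = "sboTerm" if self.fmt == "SBML" else "initial_value"
        cands = [
            el for el in self._update_targets()
            if el.attr(fresh_attr) is None and el.attributes
        ]
        if not cands:
            return False
        el = self.rng.choice(cands)
        value = (f"SBO:{self.rng.randint(1000000, 9999999)}"
                 if fresh_attr == "sboTerm" else f"{self.rng.randint(0, 99)}")
        el.set_attr(fresh_attr, value)
        self.claimed.add(id(el))
        self.a_claimed.add(id(self.orig_of[id(el)]))
        self.records.append(("ins_attr", el, fresh_attr, value))
        return True

    def try_delete_attribute(self) -> bool:
        optional = {"sboTerm", "boundaryCondition", "constant", "reversible",
                    "hasOnlySubstanceUnits", "outside", "public_interface",
                    "initial_value", "exponent", "scale"}
        cands = []
        for el in self._update_targets():
            idattr = _identity_attr(el)
            for a in el.attributes:
                if a.label in optional and a.label != idattr:
                    cands.append((el, a))
        if not cands:
            return False
        el, a = self.rng.choice(cands)
        self.records.append(
            ("del_attr", el, self.orig_of[id(el)], a.label, a.value)
        )
        el.attributes.remove(a)
        self.claimed.add(id(el))
        self.a_claimed.add(id(self.orig_of[id(el)]))
        return True

    def try_insert_text(self) -> bool:
        # only inside verbatim containers, and never adjacent to another
        # text node (adjacent text would merge on reparse)
        cands = []
        for el in self._update_targets():
            name = local_name(el.label)
            if name != "p":
                continue
            if el.children:
                continue
            cands.append(el)
        if not cands:
            return False
        el = self.rng.choice(cands)
        node = _text(f"added text {self._fresh_id('t')}")
        el.children.append(node)
        self.b_parent[id(node)] = el
        self.claimed.add(id(el))
        self.a_claimed.add(id(self.orig_of[id(el)]))
        self.records.append(("ins_text", node))
        return True

    def try_delete_text(self) -> bool:
        cands = []
        for el in self._update_targets():
            if el.children and el.children[-1].kind == "text":
                cands.append(el)
        if not cands:
            return False
        el = self.rng.choice(cands)
        t = el.children[-1]
        self.records.append(("del_text", t, self.orig_of[id(t)]))
        el.children.remove(t)
        self.claimed.add(id(el))
        self.a_claimed.add(id(self.orig_of[id(t)]))
        return True

    def try_move(self) -> bool:
        if self.rng.random() < 0.5 and self._try_move_cross_parent():
            return True
        return self._try_move_same_parent() or self._try_move_cross_parent()

    def _movable(self, el: XmlNode) -> bool:
        return (
            id(el) in self.orig_of
            and _identity_attr(el) is not None
            and self._free_subtree(el)
        )

    def _try_move_cross_parent(self) -> bool:
        pairs = []
        if self.fmt == "SBML":
            lists = [
                el for el in self._elements()
                if local_name(el.label) == "listOfParameters"
                and self._container_ok(el)
            ]
            for src in lists:
                for dst in lists:
                    if src is dst:
                        continue
                    for c in src.element_children():
                        if local_name(c.label) == "parameter" and self._movable(c):
                            pairs.append((c, dst))
        else:
            comps = [
                el for el in self._elements()
                if local_name(el.label) == "component" and self._container_ok(el)
                and id(el) in self.orig_of
            ]
            for src in comps:
                for dst in comps:
                    if src is dst:
                        continue
                    for c in src.element_children():
                        if local_name(c.label) != "variable" or not self._movable(c):
                            continue
                        name = c.attr("name")
                        if any(d.attr("name") == name for d in dst.element_children()):
                            continue
                        pairs.append((c, dst))
        if not pairs:
            return False
        el, dst = self.rng.choice(pairs)
        src = self.b_parent[id(el)]
        src.children.remove(el)
        pos = self.rng.randrange(len(dst.children) + 1)
        dst.children.insert(pos, el)
        self.b_parent[id(el)] = dst
        self._claim_subtree(el)
        self.a_claimed |= _subtree_ids(self.orig_of[id(el)])
        self.structure_touched.add(id(src))
        self.structure_touched.add(id(dst))
        self.records.append(("move", el, self.orig_of[id(el)]))
        self._recompute_safe()
        return True

    def _try_move_same_parent(self) -> bool:
        cands = []
        for container in self._elements():
            if id(container) in self.structure_touched or not self._container_ok(container):
                continue
            kids = container.children
            if len(kids) < 3 or any(k.kind != "element" for k in kids):
                continue
            for i, c in enumerate(kids):
                if not self._movable(c):
                    continue
                if i >= 2:
                    cands.append((container, i, 0))      # jump to front
                if i <= len(kids) - 3:
                    cands.append((container, i, len(kids) - 1))  # jump to back
        if not cands:
            return False
        container, i, dest = self.rng.choice(cands)
        el = container.children.pop(i)
        if dest == 0:
            container.children.insert(0, el)
        else:
            container.children.append(el)
        self._claim_subtree(el)
        self.a_claimed |= _subtree_ids(self.orig_of[id(el)])
        self.move_frozen.add(id(container))
        self.structure_touched.add(id(container))
        self.records.append(("move", el, self.orig_of[id(el)]))
        return True

    # -- driver ------------------------------------------------------
    def plant(self) -> int:
        """Sample and apply ``spec.n_edits`` edits; returns applied count."""
        attempts_by_kind = {
            ("insert", "element"): self.try_insert_element,
            ("insert", "attribute"): self.try_insert_attribute,
            ("insert", "text"): self.try_insert_text,
            ("delete", "element"): self.try_delete_element,
            ("delete", "attribute"): self.try_delete_attribute,
            ("delete", "text"): self.try_delete_text,
            ("move", "element"): self.try_move,
        }
        applied = 0
        for _ in range(self.spec.n_edits):
            done = False
            for _attempt in range(60):
                op = self.rng.choices(
                    list(self.spec.op_mix), weights=list(self.spec.op_mix.values())
                )[0]
                if op == "update":
                    if self.rng.random() < self.spec.notes_bias:
                        done = self.try_update_text()
                    else:
                        ent = self.rng.choices(["attribute", "text"],
                                               weights=[0.8, 0.2])[0]
                        done = (self.try_update_attribute() if ent == "attribute"
                                else self.try_update_text())
                elif op == "move":
                    done = self.try_move()
                else:
                    ent = self.rng.choices(
                        list(self.spec.entity_mix),
                        weights=list(self.spec.entity_mix.values()),
                    )[0]
                    done = attempts_by_kind[(op, ent)]()
                if done:
                    break
            if not done:
                done = self.try_insert_element()  # always applicable fallback
            if done:
                applied += 1
        return applied

    # -- ledger ------------------------------------------------------
    def ledger_ops(self) -> list[DiffOp]:
        finalize_tree(self.b_root)
        b_parent = {id(self.b_root): None}
        for el in iter_elements(self.b_root):
            for c in el.children:
                b_parent[id(c)] = el

        def content_pos(n: XmlNode) -> int:
            return b_parent[id(n)].children.index(n)

        ops: list[DiffOp] = []
        for rec in self.records:
            kind = rec[0]
            if kind == "ins_el":
                node = rec[1]
                first = True
                for el in iter_elements(node):
                    ops.append(DiffOp(
                        "insert", "element", new_path=el.path, new_value=el.label,
                        triggered=not first, new_pos=content_pos(el)))
                    for a in el.attributes:
                        ops.append(DiffOp("insert", "attribute", new_path=a.path,
                                          new_value=a.value, triggered=True))
                    for t in el.text_children():
                        ops.append(DiffOp("insert", "text", new_path=t.path,
                                          new_value=t.value, triggered=True,
                                          new_pos=content_pos(t)))
                    first = False
            elif kind == "del_el":
                _, _b_el, a_el = rec
                first = True
                for el in iter_elements(a_el):
                    ops.append(DiffOp("delete", "element", old_path=el.path,
                                      old_value=el.label, triggered=not first))
                    for a in el.attributes:
                        ops.append(DiffOp("delete", "attribute", old_path=a.path,
                                          old_value=a.value, triggered=True))
                    for t in el.text_children():
                        ops.append(DiffOp("delete", "text", old_path=t.path,
                                          old_value=t.value, triggered=True))
                    first = False
            elif kind == "upd_attr":
                _, b_el, a_el, name, old, new = rec
                ops.append(DiffOp("update", "attribute",
                                  old_path=f"{a_el.path}/@{name}",
                                  new_path=f"{b_el.path}/@{name}",
                                  old_value=old, new_value=new))
            elif kind == "upd_text":
                _, b_t, a_t, old, new = rec
                ops.append(DiffOp("update", "text", old_path=a_t.path,
                                  new_path=b_t.path, old_value=old, new_value=new))
            elif kind == "ins_attr":
                _, b_el, name, value = rec
                ops.append(DiffOp("insert", "attribute",
                                  new_path=f"{b_el.path}/@{name}", new_value=value))
            elif kind == "del_attr":
                _, _b_el, a_el, name, value = rec
                ops.append(DiffOp("delete", "attribute",
                                  old_path=f"{a_el.path}/@{name}", old_value=value))
            elif kind == "ins_text":
                node = rec[1]
                ops.append(DiffOp("insert", "text", new_path=node.path,
                                  new_value=node.value, new_pos=content_pos(node)))
            elif kind == "del_text":
                _, _b_t, a_t = rec
                ops.append(DiffOp("delete", "text", old_path=a_t.path,
                                  old_value=a_t.value))
            elif kind == "move":
                _, b_el, a_el = rec
                ops.append(DiffOp("move", "element", old_path=a_el.path,
                                  new_path=b_el.path, new_pos=content_pos(b_el)))
        return ops


def plant_edits(
    doc: ModelDocument,
    spec: EditSpec,
    rng: random.Random,
    version_id: str,
    timestamp: datetime,
    fresh_counter: int = 0,
) -> tuple[ModelDocument, list[DiffOp], int]:
    """One transition: edited copy of ``doc``, its planted ops, counter state."""
    spec.validate()
    planter = _Planter(doc, spec, rng, fresh_counter)
    planter.plant()
    ops = planter.ledger_ops()
    new_doc = ModelDocument(
        format=doc.format,
        model_id=doc.model_id,
        version_id=version_id,
        timestamp=timestamp,
        root=planter.b_root,
        source_uri=f"synthetic://{doc.model_id}/{version_id}",
    )
    return new_doc, ops, planter.fresh


def generate_history(
    seed_doc: ModelDocument,
    n_versions: int,
    edit_spec: EditSpec,
    rng_seed: int = 0,
    step: timedelta = timedelta(days=7),
) -> tuple[list[ModelDocument], GroundTruthLedger]:
    """Version chain with planted ground truth; timestamps strictly increase."""
    if n_versions < 1:
        raise ValueError("n_versions must be >= 1")
    rng = random.Random(rng_seed)
    versions = [seed_doc]
    ledger = GroundTruthLedger(model_id=seed_doc.model_id)
    fresh = 0
    prev_counts = count_entities(seed_doc)
    for i in range(1, n_versions):
        ts = seed_doc.timestamp + i * step
        nxt, ops, fresh = plant_edits(
            versions[-1], edit_spec, rng, f"v{i}", ts, fresh
        )
        versions.append(nxt)
        ledger.transitions.append(ops)
        counts = count_entities(nxt)
        ledger.count_deltas.append({
            f: getattr(counts, f) - getattr(prev_counts, f)
            for f in EntityCounts.COUNT_FIELDS
        })
        prev_counts = counts
    return versions, ledger


# ----------------------------------------------------------------------
# corpus emission and recovery scoring
# ----------------------------------------------------------------------

def write_corpus(
    out_dir: str | Path,
    n_models: int = 10,
    n_versions: int = 4,
    edit_spec: Optional[EditSpec] = None,
    formats: str = "mixed",
    rng_seed: int = 0,
    size_params: Optional[dict] = None,
) -> list[Path]:
    """Emit the ingestion layout plus per-model ground-truth ledgers.

    Layout: ``<out>/<repo>/<model_id>/manifest.json``,
    ``<out>/<repo>/<model_id>/<NNN>_<version_id>/model.xml`` and
    ``<out>/<repo>/<model_id>/ledger.json``.  SBML models land in
    ``biomodels-like``, CellML models in ``pmr-like``.
    """
    out = Path(out_dir)
    spec = edit_spec or EditSpec()
    written = []
    for i in range(n_models):
        if formats == "mixed":
            fmt = "SBML" if i % 2 == 0 else "CellML"
        else:
            fmt = formats.upper().replace("CELLML", "CellML")
        repo = "biomodels-like" if fmt == "SBML" else "pmr-like"
        model_id = f"M{i:04d}"
        seed = generate_seed_model(
            fmt, size_params, rng_seed=rng_seed * 1000 + i, model_id=model_id,
            timestamp=EPOCH + timedelta(days=30 * i),
        )
        versions, ledger = generate_history(
            seed, n_versions, spec, rng_seed=rng_seed * 1000 + i + 1
        )
        mdir = out / repo / model_id
        mdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "model_id": model_id,
            "repository": repo,
            "curation_status": "curated" if i % 3 == 0 else "non-curated",
            "versions": [],
        }
        for j, doc in enumerate(versions):
            vdir = mdir / f"{j:03d}_{doc.version_id}"
            vdir.mkdir(exist_ok=True)
            (vdir / "model.xml").write_text(canonical_serialize(doc), encoding="utf-8")
            manifest["versions"].append({
                "version_id": doc.version_id,
                "timestamp": doc.timestamp.isoformat(),
                "dir": vdir.name,
            })
        (mdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )
        (mdir / "ledger.json").write_text(ledger.to_json(), encoding="utf-8")
        written.append(mdir)
    return written


def ops_multiset(ops: list[DiffOp]) -> dict:
    """Multiset of full op identities, for exact-recovery comparison."""
    out: dict = {}
    for op in ops:
        k = op.key()
        out[k] = out.get(k, 0) + 1
    return out


def path_level_scores(
    truth: list[DiffOp], predicted: list[DiffOp]
) -> tuple[float, float, float]:
    """(precision, recall, F1) over (op_type, anchor path) pairs."""
    def bag(ops):
        b: dict = {}
        for op in ops:
            k = (op.op_type, op.old_path or op.new_path)
            b[k] = b.get(k, 0) + 1
        return b

    tb, pb = bag(truth), bag(predicted)
    tp = sum(min(n, pb.get(k, 0)) for k, n in tb.items())
    prec = tp / sum(pb.values()) if pb else 1.0
    rec = tp / sum(tb.values()) if tb else 1.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1
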