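"""Typed edit scripts between two versions of a model.

Implements three-stage tree matching (identity attributes, structural
propagation, similarity fallback), derivation of insert/delete/update/move
operations with *triggered* flags for operations implied by a subtree
insert or delete, a longest-common-subsequence line diff, and the patch
operator ``apply_delta`` used as the round-trip correctness oracle.

Matching strategy
-----------------
1. Exact match on identity attributes (``id``, ``metaid``, ``name``) with
   equal element label, for keys unique in both trees.
2. Fixpoint propagation along matched pairs: parents with agreeing labels,
   children unique by (label, identity value) or by label among the
   unmatched children of a matched pair.
3. Greedy similarity matching of residual same-label elements by
   descendant-token Jaccard similarity >= 0.7, ties broken by document
   order; followed by another propagation round.

Move semantics: a matched element moves when its parent changes, or when
its position within the matched sibling sequence breaks the longest
increasing subsequence of that sequence (so pure inserts/deletes never
cause spurious moves, and sibling reorders are reported minimally).

``DiffOp.new_pos`` records the 0-based content position (elements + text
nodes) of an inserted or moved node within its new parent.  It is not part
of the minimal operation description but makes deltas self-contained for
patching: same-label indices alone cannot place a node among siblings with
different labels.
"""

from __future__ import annotations

import copy
import json
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional
from xml.sax.saxutils import quoteattr

from .model_io import (
    ModelDocument,
    XmlNode,
    assign_paths,
    canonical_serialize,
    finalize_tree,
    iter_elements,
    local_name,
)

__all__ = [
    "DiffOp",
    "Delta",
    "TreeMatching",
    "ModelIdMismatchError",
    "InconsistentDeltaError",
    "match_trees",
    "diff",
    "diff_trees",
    "line_diff",
    "apply_delta",
]

OP_TYPES = ("insert", "delete", "update", "move")
ENTITY_KINDS = ("element", "attribute", "text")

#: attributes used for pass-1 identity matching, in priority order
IDENTITY_ATTRIBUTES = ("id", "metaid", "name")

JACCARD_THRESHOLD = 0.7


class ModelIdMismatchError(ValueError):
    """Versions of distinct models are not comparable histories."""


class InconsistentDeltaError(ValueError):
    """The delta does not apply to the given base document."""


@dataclass(frozen=True)
class DiffOp:
    """One typed change operation.

    insert: ``new_path`` only (``new_value`` carries the element label,
    attribute value or text content); delete: ``old_path`` only; update and
    move carry both paths.  ``triggered`` flags operations implied by an
    enclosing subtree insert/delete.
    """

    op_type: str
    entity_kind: str
    old_path: Optional[str] = None
    new_path: Optional[str] = None
    old_value: Optional[str] = None
    new_value: Optional[str] = None
    triggered: bool = False
    new_pos: Optional[int] = None

    def key(self) -> tuple:
        """Multiset identity used for ledger/diff comparison."""
        return (
            self.op_type,
            self.entity_kind,
            self.old_path,
            self.new_path,
            self.old_value,
            self.new_value,
            self.triggered,
            self.new_pos,
        )

    def to_dict(self) -> dict:
        d = {"op_type": self.op_type, "entity_kind": self.entity_kind}
        for f in ("old_path", "new_path", "old_value", "new_value", "new_pos"):
            v = getattr(self, f)
            if v is not None:
                d[f] = v
        d["triggered"] = self.triggered
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DiffOp":
        return cls(
            op_type=d["op_type"],
            entity_kind=d["entity_kind"],
            old_path=d.get("old_path"),
            new_path=d.get("new_path"),
            old_value=d.get("old_value"),
            new_value=d.get("new_value"),
            triggered=bool(d.get("triggered", False)),
            new_pos=d.get("new_pos"),
        )


@dataclass
class Delta:
    """The full edit script between two versions of one model."""

    model_id: str
    version_from: str
    version_to: str
    ops: list[DiffOp] = field(default_factory=list)
    line_inserts: int = 0
    line_deletes: int = 0

    @property
    def summary(self) -> dict:
        """Tallies by (op_type x entity_kind) plus the triggered count."""
        s = {(o, k): 0 for o in OP_TYPES for k in ENTITY_KINDS}
        triggered = 0
        for op in self.ops:
            s[(op.op_type, op.entity_kind)] += 1
            if op.triggered:
                triggered += 1
        out = {f"{o}_{k}": n for (o, k), n in s.items()}
        out["triggered"] = triggered
        for o in OP_TYPES:
            out[o] = sum(s[(o, k)] for k in ENTITY_KINDS)
        out["total"] = len(self.ops)
        return out

    def is_empty(self) -> bool:
        return not self.ops and self.line_inserts == 0 and self.line_deletes == 0

    # -- export ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "version_from": self.version_from,
                "version_to": self.version_to,
                "line_inserts": self.line_inserts,
                "line_deletes": self.line_deletes,
                "summary": self.summary,
                "ops": [op.to_dict() for op in self.ops],
            },
            indent=2,
            sort_keys=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "Delta":
        d = json.loads(text)
        return cls(
            model_id=d["model_id"],
            version_from=d["version_from"],
            version_to=d["version_to"],
            ops=[DiffOp.from_dict(o) for o in d["ops"]],
            line_inserts=d.get("line_inserts", 0),
            line_deletes=d.get("line_deletes", 0),
        )

    def to_xml_patch(self) -> str:
        lines = ['<?xml version="1.0" encoding="UTF-8"?>']
        lines.append(
            f"<patch model={quoteattr(self.model_id)} "
            f"from={quoteattr(self.version_from)} to={quoteattr(self.version_to)}>"
        )
        for op in self.ops:
            parts = [f'op="{op.op_type}"', f'kind="{op.entity_kind}"']
            if op.old_path is not None:
                parts.append(f"oldPath={quoteattr(op.old_path)}")
            if op.new_path is not None:
                parts.append(f"newPath={quoteattr(op.new_path)}")
            if op.old_value is not None:
                parts.append(f"oldValue={quoteattr(op.old_value)}")
            if op.new_value is not None:
                parts.append(f"newValue={quoteattr(op.new_value)}")
            if op.new_pos is not None:
                parts.append(f'pos="{op.new_pos}"')
            parts.append(f'triggered="{"true" if op.triggered else "false"}"')
            lines.append(f'  <operation {" ".join(parts)}/>')
        lines.append("</patch>")
        return "\n".join(lines) + "\n"

    def to_text(self, include_triggered: bool = True) -> str:
        """Human-readable one-line-per-operation report."""
        head = [
            f"model {self.model_id}: {self.version_from} -> {self.version_to}",
            f"line diff: +{self.line_inserts} -{self.line_deletes}",
        ]
        ops = [o for o in self.ops if include_triggered or not o.triggered]
        if not ops:
            head.append("0 operations")
        else:
            head.append(f"{len(ops)} operations:")
        for op in ops:
            loc = op.new_path or op.old_path or ""
            detail = ""
            if op.op_type == "update":
                detail = f" {op.old_value!r} -> {op.new_value!r}"
            elif op.op_type == "move":
                detail = f" from {op.old_path}"
            flag = " [triggered]" if op.triggered else ""
            head.append(f"  {op.op_type} {op.entity_kind} {loc}{detail}{flag}")
        return "\n".join(head) + "\n"


# ----------------------------------------------------------------------
# tree matching
# ----------------------------------------------------------------------

class TreeMatching:
    """Partial one-to-one element correspondence between two trees."""

    def __init__(self) -> None:
        self.a2b: dict[int, XmlNode] = {}
        self.b2a: dict[int, XmlNode] = {}

    def add(self, a: XmlNode, b: XmlNode) -> None:
        self.a2b[id(a)] = b
        self.b2a[id(b)] = a

    def matched_a(self, a: XmlNode) -> bool:
        return id(a) in self.a2b

    def matched_b(self, b: XmlNode) -> bool:
        return id(b) in self.b2a

    def image(self, a: XmlNode) -> Optional[XmlNode]:
        return self.a2b.get(id(a))

    def preimage(self, b: XmlNode) -> Optional[XmlNode]:
        return self.b2a.get(id(b))

    def pairs(self) -> list[tuple[XmlNode, XmlNode]]:
        return [(a, self.a2b[id(a)]) for a in self._a_order if id(a) in self.a2b]

    _a_order: list[XmlNode] = []


def _identity_key(el: XmlNode) -> Optional[tuple]:
    for a in IDENTITY_ATTRIBUTES:
        v = el.attr(a)
        if v is not None:
            return (el.label, a, v)
    return None


def _identity_compatible(x: XmlNode, y: XmlNode) -> bool:
    """Structural propagation must not pair nodes with conflicting ids;
    conflicting pairs are left to the similarity pass (possible renames)."""
    kx, ky = _identity_key(x), _identity_key(y)
    return kx is None or ky is None or kx == ky


def _parent_map(root: XmlNode) -> dict[int, Optional[XmlNode]]:
    pm: dict[int, Optional[XmlNode]] = {id(root): None}
    for el in iter_elements(root):
        for c in el.children:
            pm[id(c)] = el
    return pm


def _token_set(el: XmlNode, cache: dict[int, frozenset]) -> frozenset:
    cached = cache.get(id(el))
    if cached is not None:
        return cached
    toks = {f"e:{el.label}"}
    toks.update(f"a:{a.label}={a.value}" for a in el.attributes)
    for c in el.children:
        if c.kind == "text":
            toks.add(f"t:{c.value}")
        else:
            toks.update(_token_set(c, cache))
    fs = frozenset(toks)
    cache[id(el)] = fs
    return fs


def match_trees(a_root: XmlNode, b_root: XmlNode) -> TreeMatching:
    """Compute the partial one-to-one element correspondence.

    Roots are always mapped; mapped nodes have equal kind (element).
    Deterministic: equal inputs yield the identical mapping.
    """
    m = TreeMatching()
    a_elems = list(iter_elements(a_root))
    b_elems = list(iter_elements(b_root))
    a_order = {id(e): i for i, e in enumerate(a_elems)}
    b_order = {id(e): i for i, e in enumerate(b_elems)}
    m._a_order = a_elems
    a_parent = _parent_map(a_root)
    b_parent = _parent_map(b_root)

    m.add(a_root, b_root)

    # pass 1: globally unique identity keys
    def key_index(elems):
        idx: dict[tuple, list[XmlNode]] = {}
        for e in elems:
            k = _identity_key(e)
            if k is not None:
                idx.setdefault(k, []).append(e)
        return idx

    a_ids = key_index(a_elems)
    b_ids = key_index(b_elems)
    for k, ea in a_ids.items():
        eb = b_ids.get(k)
        if eb and len(ea) == 1 and len(eb) == 1:
            if not m.matched_a(ea[0]) and not m.matched_b(eb[0]):
                m.add(ea[0], eb[0])

    def propagate() -> bool:
        """Pass 2: fixpoint propagation along matched pairs."""
        changed_any = False
        changed = True
        while changed:
            changed = False
            for a in a_elems:
                b = m.image(a)
                if b is None:
                    continue
                # parents
                pa, pb = a_parent[id(a)], b_parent[id(b)]
                if (
                    pa is not None
                    and pb is not None
                    and not m.matched_a(pa)
                    and not m.matched_b(pb)
                    and pa.label == pb.label
                    and _identity_compatible(pa, pb)
                ):
                    m.add(pa, pb)
                    changed = True
                # children, unique by identity key then by label
                ca = [c for c in a.element_children() if not m.matched_a(c)]
                cb = [c for c in b.element_children() if not m.matched_b(c)]
                if not ca or not cb:
                    continue
                for keyfn in (_identity_key, lambda e: e.label):
                    ka: dict = {}
                    for c in ca:
                        k = keyfn(c)
                        if k is not None:
                            ka.setdefault(k, []).append(c)
                    kb: dict = {}
                    for c in cb:
                        k = keyfn(c)
                        if k is not None:
                            kb.setdefault(k, []).append(c)
                    for k, la in ka.items():
                        lb = kb.get(k)
                        if lb and len(la) == 1 and len(lb) == 1:
                            if (
                                not m.matched_a(la[0])
                                and not m.matched_b(lb[0])
                                and _identity_compatible(la[0], lb[0])
                            ):
                                m.add(la[0], lb[0])
                                changed = True
                    ca = [c for c in ca if not m.matched_a(c)]
                    cb = [c for c in cb if not m.matched_b(c)]
            changed_any = changed_any or changed
        return changed_any

    propagate()

    # pass 3 + re-propagation until stable
    cache_a: dict[int, frozenset] = {}
    cache_b: dict[int, frozenset] = {}
    for _ in range(5):
        res_a: dict[str, list[XmlNode]] = {}
        for e in a_elems:
            if not m.matched_a(e):
                res_a.setdefault(e.label, []).append(e)
        res_b: dict[str, list[XmlNode]] = {}
        for e in b_elems:
            if not m.matched_b(e):
                res_b.setdefault(e.label, []).append(e)
        candidates = []
        for label, la in res_a.items():
            lb = res_b.get(label)
            if not lb:
                continue
            for ea in la:
                ta = _token_set(ea, cache_a)
                for eb in lb:
                    tb = _token_set(eb, cache_b)
                    union = len(ta | tb)
                    sim = len(ta & tb) / union if union else 1.0
                    if sim >= JACCARD_THRESHOLD:
                        candidates.append((-sim, a_order[id(ea)], b_order[id(eb)], ea, eb))
        candidates.sort(key=lambda t: t[:3])
        added = False
        for _, _, _, ea, eb in candidates:
            if not m.matched_a(ea) and not m.matched_b(eb):
                m.add(ea, eb)
                added = True
        if not added:
            break
        propagate()
    return m


# ----------------------------------------------------------------------
# LIS (patience) used for sibling move detection
# ----------------------------------------------------------------------

def _lis_indices(seq: list[int]) -> set[int]:
    """Indices of one longest strictly increasing subsequence of ``seq``."""
    if not seq:
        return set()
    tails: list[int] = []       # values
    tails_idx: list[int] = []   # index of value in seq
    prev = [-1] * len(seq)
    for i, v in enumerate(seq):
        j = bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = set()
    i = tails_idx[-1]
    while i != -1:
        out.add(i)
        i = prev[i]
    return out


# ----------------------------------------------------------------------
# diff
# ----------------------------------------------------------------------

def _content_pos(parent_map: dict, node: XmlNode) -> int:
    parent = parent_map[id(node)]
    return parent.children.index(node)


def diff_trees(a_root: XmlNode, b_root: XmlNode) -> list[DiffOp]:
    """Edit script between two canonicalized trees (element roots)."""
    m = match_trees(a_root, b_root)
    a_parent = _parent_map(a_root)
    b_parent = _parent_map(b_root)
    ops: list[DiffOp] = []

    # --- deletes: unmatched elements in a --------------------------
    for el in iter_elements(a_root):
        if m.matched_a(el):
            continue
        parent = a_parent[id(el)]
        triggered = parent is not None and not m.matched_a(parent)
        ops.append(
            DiffOp("delete", "element", old_path=el.path, old_value=el.label,
                   triggered=triggered)
        )
        for a in el.attributes:
            ops.append(
                DiffOp("delete", "attribute", old_path=a.path, old_value=a.value,
                       triggered=True)
            )
        for t in el.text_children():
            ops.append(
                DiffOp("delete", "text", old_path=t.path, old_value=t.value,
                       triggered=True)
            )

    # --- inserts: unmatched elements in b --------------------------
    for el in iter_elements(b_root):
        if m.matched_b(el):
            continue
        parent = b_parent[id(el)]
        triggered = parent is not None and not m.matched_b(parent)
        ops.append(
            DiffOp("insert", "element", new_path=el.path, new_value=el.label,
                   triggered=triggered, new_pos=_content_pos(b_parent, el))
        )
        for a in el.attributes:
            ops.append(
                DiffOp("insert", "attribute", new_path=a.path, new_value=a.value,
                       triggered=True)
            )
        for t in el.text_children():
            ops.append(
                DiffOp("insert", "text", new_path=t.path, new_value=t.value,
                       triggered=True, new_pos=_content_pos(b_parent, t))
            )

    # --- matched pairs: attributes, text, label updates, moves ------
    for x, y in m.pairs():
        if x.label != y.label:
            ops.append(
                DiffOp("update", "element", old_path=x.path, new_path=y.path,
                       old_value=x.label, new_value=y.label)
            )
        ax = {a.label: a for a in x.attributes}
        ay = {a.label: a for a in y.attributes}
        for name in sorted(set(ax) | set(ay)):
            if name not in ay:
                ops.append(
                    DiffOp("delete", "attribute", old_path=ax[name].path,
                           old_value=ax[name].value)
                )
            elif name not in ax:
                ops.append(
                    DiffOp("insert", "attribute", new_path=ay[name].path,
                           new_value=ay[name].value)
                )
            elif ax[name].value != ay[name].value:
                ops.append(
                    DiffOp("update", "attribute", old_path=ax[name].path,
                           new_path=ay[name].path, old_value=ax[name].value,
                           new_value=ay[name].value)
                )
        tx = x.text_children()
        ty = y.text_children()
        for i in range(min(len(tx), len(ty))):
            if tx[i].value != ty[i].value:
                ops.append(
                    DiffOp("update", "text", old_path=tx[i].path,
                           new_path=ty[i].path, old_value=tx[i].value,
                           new_value=ty[i].value)
                )
        for t in tx[len(ty):]:
            ops.append(DiffOp("delete", "text", old_path=t.path, old_value=t.value))
        for t in ty[len(tx):]:
            ops.append(
                DiffOp("insert", "text", new_path=t.path, new_value=t.value,
                       new_pos=_content_pos(b_parent, t))
            )
        # parent-change moves
        px, py = a_parent[id(x)], b_parent[id(y)]
        if px is not None and py is not None and m.image(px) is not py:
            ops.append(
                DiffOp("move", "element", old_path=x.path, new_path=y.path,
                       new_pos=_content_pos(b_parent, y))
            )

    # --- sibling-order moves within each matched parent -------------
    for p, q in m.pairs():
        stay = []
        for c in p.element_children():
            d = m.image(c)
            if d is not None and b_parent[id(d)] is q:
                stay.append((c, d))
        if len(stay) < 2:
            continue
        b_positions = [q.children.index(d) for _, d in stay]
        keep = _lis_indices(b_positions)
        for i, (c, d) in enumerate(stay):
            if i not in keep:
                ops.append(
                    DiffOp("move", "element", old_path=c.path, new_path=d.path,
                           new_pos=q.children.index(d))
                )
    return ops


def diff(a: ModelDocument, b: ModelDocument) -> Delta:
    """Typed edit script plus line-diff counts between two model versions."""
    if a.model_id != b.model_id:
        raise ModelIdMismatchError(
            f"cannot diff distinct models {a.model_id!r} vs {b.model_id!r}"
        )
    ops = diff_trees(a.root, b.root)
    li, ld = line_diff(canonical_serialize(a), canonical_serialize(b))
    return Delta(
        model_id=a.model_id,
        version_from=a.version_id,
        version_to=b.version_id,
        ops=ops,
        line_inserts=li,
        line_deletes=ld,
    )


# ----------------------------------------------------------------------
# line diff (Myers O(ND); counts match the LCS model exactly)
# ----------------------------------------------------------------------

def line_diff(text_a: str, text_b: str) -> tuple[int, int]:
    """(line_inserts, line_deletes) under the classical LCS diff model."""
    a = text_a.splitlines()
    b = text_b.splitlines()
    # trim common prefix/suffix
    lo = 0
    while lo < len(a) and lo < len(b) and a[lo] == b[lo]:
        lo += 1
    hi = 0
    while (
        hi < len(a) - lo and hi < len(b) - lo and a[-1 - hi] == b[-1 - hi]
    ):
        hi += 1
    a = a[lo: len(a) - hi]
    b = b[lo: len(b) - hi]
    n, m_ = len(a), len(b)
    if n == 0 or m_ == 0:
        return m_, n
    d = _myers_distance(a, b)
    lcs = (n + m_ - d) // 2
    return m_ - lcs, n - lcs


def _myers_distance(a: list, b: list) -> int:
    n, m_ = len(a), len(b)
    max_d = n + m_
    v = {1: 0}
    for d in range(max_d + 1):
        for k in range(-d, d + 1, 2):
            if k == -d or (k != d and v.get(k - 1, -1) < v.get(k + 1, -1)):
                x = v.get(k + 1, 0)
            else:
                x = v.get(k - 1, 0) + 1
            y = x - k
            while x < n and y < m_ and a[x] == b[y]:
                x += 1
                y += 1
            v[k] = x
            if x >= n and y >= m_:
                return d
    return max_d  # pragma: no cover


# ----------------------------------------------------------------------
# patching
# ----------------------------------------------------------------------

def _path_depth(path: str) -> int:
    return path.count("/")


def _resolve(root: XmlNode, path: str) -> XmlNode:
    """Resolve a canonical path in the current tree state."""
    segs = path.strip("/").split("/")
    node = root
    if not segs or segs[0] != f"{local_name(root.label)}[1]":
        raise InconsistentDeltaError(f"path {path!r} does not start at root")
    for seg in segs[1:]:
        if seg.startswith("@"):
            name = seg[1:]
            for a in node.attributes:
                if a.label == name:
                    return a
            raise InconsistentDeltaError(f"attribute not found: {path}")
        if seg.startswith("text()["):
            i = int(seg[len("text()["):-1])
            texts = node.text_children()
            if i > len(texts):
                raise InconsistentDeltaError(f"text node not found: {path}")
            return texts[i - 1]
        name, _, idx = seg.partition("[")
        i = int(idx[:-1])
        found = [c for c in node.element_children() if local_name(c.label) == name]
        if i > len(found):
            raise InconsistentDeltaError(f"element not found: {path}")
        node = found[i - 1]
    return node


def apply_delta(a: ModelDocument, delta: Delta) -> ModelDocument:
    """Apply an edit script produced by :func:`diff` to its base document.

    Contract: ``apply_delta(A, diff(A, B))`` canonical-equals ``B``.
    Raises :class:`InconsistentDeltaError` when the delta does not fit the
    base (unknown paths, value mismatches, bad positions).
    """
    root = copy.deepcopy(a.root)
    pathmap: dict[str, XmlNode] = {}
    parent_of: dict[int, Optional[XmlNode]] = {id(root): None}
    for el in iter_elements(root):
        pathmap[el.path] = el
        for at in el.attributes:
            pathmap[at.path] = at
            parent_of[id(at)] = el
        for c in el.children:
            parent_of[id(c)] = el
            if c.kind == "text":
                pathmap[c.path] = c

    def need(path: Optional[str]) -> XmlNode:
        if path is None or path not in pathmap:
            raise InconsistentDeltaError(f"path not found in base: {path}")
        return pathmap[path]

    detached: list[XmlNode] = []
    placements: list[tuple[int, str, int, XmlNode]] = []  # depth, parent path, pos, node
    attr_inserts: list[tuple[int, str, str, str]] = []    # depth, parent path, name, value

    def split_parent(path: str) -> tuple[str, str]:
        head, _, seg = path.rpartition("/")
        return head, seg

    for op in delta.ops:
        if op.op_type == "update":
            node = need(op.old_path)
            if op.entity_kind == "element":
                if node.label != op.old_value:
                    raise InconsistentDeltaError(f"label mismatch at {op.old_path}")
                node.label = op.new_value  # type: ignore[assignment]
            else:
                if node.value != op.old_value:
                    raise InconsistentDeltaError(
                        f"value mismatch at {op.old_path}: "
                        f"{node.value!r} != {op.old_value!r}"
                    )
                node.value = op.new_value
        elif op.op_type == "delete":
            if op.triggered:
                continue  # implied by the subtree root delete
            node = need(op.old_path)
            parent = parent_of[id(node)]
            if op.entity_kind == "attribute":
                if node.value != op.old_value:
                    raise InconsistentDeltaError(f"value mismatch at {op.old_path}")
                parent.attributes.remove(node)
            else:
                detached.append(node)
        elif op.op_type == "move":
            node = need(op.old_path)
            detached.append(node)
            head, _ = split_parent(op.new_path)
            placements.append((_path_depth(op.new_path), head, op.new_pos, node))
        elif op.op_type == "insert":
            head, seg = split_parent(op.new_path)
            depth = _path_depth(op.new_path)
            if op.entity_kind == "attribute":
                attr_inserts.append((depth, head, seg[1:], op.new_value or ""))
            elif op.entity_kind == "text":
                node = XmlNode(kind="text", label="#text", value=op.new_value)
                placements.append((depth, head, op.new_pos, node))
            else:
                if op.new_value is None:
                    raise InconsistentDeltaError(
                        f"element insert without label at {op.new_path}"
                    )
                node = XmlNode(kind="element", label=op.new_value)
                placements.append((depth, head, op.new_pos, node))
        else:  # pragma: no cover
            raise InconsistentDeltaError(f"unknown op type {op.op_type!r}")

    for node in detached:
        parent = parent_of[id(node)]
        if parent is None or node not in parent.children:
            raise InconsistentDeltaError(f"cannot detach node at {node.path}")
        parent.children.remove(node)

    for depth, parent_path, pos, node in sorted(
        placements, key=lambda t: (t[0], t[1], t[2] if t[2] is not None else 0)
    ):
        parent = _resolve(root, parent_path)
        if parent.kind != "element":
            raise InconsistentDeltaError(f"placement parent not an element: {parent_path}")
        if pos is None or pos > len(parent.children):
            raise InconsistentDeltaError(
                f"bad placement position {pos} under {parent_path}"
            )
        parent.children.insert(pos, node)
        # freshly inserted subtrees receive children resolved by path later;
        # recompute paths incrementally so deeper resolutions succeed
        assign_paths(root)

    for depth, parent_path, name, value in sorted(attr_inserts):
        parent = _resolve(root, parent_path)
        if parent.attr(name) is not None:
            raise InconsistentDeltaError(f"attribute already present: {parent_path}/@{name}")
        parent.set_attr(name, value)

    finalize_tree(root)
    return ModelDocument(
        format=a.format,
        model_id=a.model_id,
        version_id=delta.version_to,
        timestamp=a.timestamp,
        root=root,
        source_uri=a.source_uri,
    )
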