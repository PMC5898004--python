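"""Independent oracles used by the test suite.

These deliberately share no code with the production algorithms:
a quadratic dynamic-programming LCS for line-diff counts, and a
Zhang–Shasha ordered tree-edit-distance for small trees (<= ~25 nodes).
"""

from __future__ import annotations

import random

from modelevo.model_io import XmlNode


# ----------------------------------------------------------------------
# quadratic LCS
# ----------------------------------------------------------------------

def lcs_length(a: list, b: list) -> int:
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = cur[j - 1] if cur[j - 1] >= prev[j] else prev[j]
        prev = cur
    return prev[m]


def lcs_line_counts(text_a: str, text_b: str) -> tuple[int, int]:
    """(inserts, deletes) from a full DP LCS over the line sequences."""
    a = text_a.splitlines()
    b = text_b.splitlines()
    l = lcs_length(a, b)
    return len(b) - l, len(a) - l


# ----------------------------------------------------------------------
# Zhang–Shasha ordered tree edit distance
# ----------------------------------------------------------------------

class ZsNode:
    __slots__ = ("label", "children")

    def __init__(self, label, children=None):
        self.label = label
        self.children = children or []


def xml_to_zs(el: XmlNode) -> ZsNode:
    """Element tree -> ordered labelled tree: attributes and text become
    leaf children whose label embeds their value."""
    kids = [ZsNode(("attr", a.label, a.value)) for a in el.attributes]
    for c in el.children:
        if c.kind == "text":
            kids.append(ZsNode(("text", c.value)))
        else:
            kids.append(xml_to_zs(c))
    return ZsNode(("el", el.label), kids)


def _postorder(root: ZsNode):
    nodes, lmld = [], []

    def rec(n: ZsNode) -> int:
        first = None
        for c in n.children:
            idx = rec(c)
            if first is None:
                first = lmld[idx]
        nodes.append(n)
        i = len(nodes) - 1
        lmld.append(first if first is not None else i)
        return i

    rec(root)
    return nodes, lmld


def zs_distance(t1: ZsNode, t2: ZsNode) -> int:
    """Unit-cost ordered tree edit distance (insert=delete=1, relabel=1)."""
    n1, l1 = _postorder(t1)
    n2, l2 = _postorder(t2)
    kr1 = _keyroots(l1)
    kr2 = _keyroots(l2)
    td = [[0] * len(n2) for _ in range(len(n1))]

    for i in kr1:
        for j in kr2:
            _treedist(i, j, n1, n2, l1, l2, td)
    return td[len(n1) - 1][len(n2) - 1]


def _keyroots(lmld: list[int]) -> list[int]:
    seen = {}
    for i, l in enumerate(lmld):
        seen[l] = i
    return sorted(seen.values())


def _treedist(i, j, n1, n2, l1, l2, td):
    li, lj = l1[i], l2[j]
    m = i - li + 2
    n = j - lj + 2
    fd = [[0] * n for _ in range(m)]
    for x in range(1, m):
        fd[x][0] = fd[x - 1][0] + 1
    for y in range(1, n):
        fd[0][y] = fd[0][y - 1] + 1
    for x in range(1, m):
        for y in range(1, n):
            gi = li + x - 1
            gj = lj + y - 1
            if l1[gi] == li and l2[gj] == lj:
                cost = 0 if n1[gi].label == n2[gj].label else 1
                fd[x][y] = min(
                    fd[x - 1][y] + 1,
                    fd[x][y - 1] + 1,
                    fd[x - 1][y - 1] + cost,
                )
                td[gi][gj] = fd[x][y]
            else:
                fd[x][y] = min(
                    fd[x - 1][y] + 1,
                    fd[x][y - 1] + 1,
                    fd[l1[gi] - li][l2[gj] - lj] + td[gi][gj],
                )


# ----------------------------------------------------------------------
# random small trees with planted edits (for the oracle-equivalence check)
# ----------------------------------------------------------------------

def random_small_tree(rng: random.Random, max_nodes: int = 25) -> XmlNode:
    """Random generic element tree; every element carries a unique id."""
    n_nodes = rng.randint(3, max_nodes)
    counter = [0]

    def make() -> XmlNode:
        counter[0] += 1
        el = XmlNode(kind="element", label=rng.choice(["a", "b", "c", "d"]))
        el.attributes = [
            XmlNode(kind="attribute", label="id", value=f"n{counter[0]}"),
            XmlNode(kind="attribute", label="w", value=str(rng.randint(0, 9))),
        ]
        return el

    root = XmlNode(kind="element", label="root")
    root.attributes = [XmlNode(kind="attribute", label="id", value="root")]
    pool = [root]
    while counter[0] < n_nodes - 1:
        parent = rng.choice(pool)
        child = make()
        parent.children.append(child)
        pool.append(child)
    return root


def perturb_tree(root: XmlNode, rng: random.Random, n_edits: int) -> XmlNode:
    """Copy of the tree with small random planted edits; returns the copy.

    Each pair either grows or shrinks (never both): a label-agnostic
    minimal edit script may merge an unrelated delete + insert into
    relabels, which an identity-faithful differ deliberately reports as
    separate operations — mixing the two would not give a comparable
    lower bound.
    """
    import copy

    t = copy.deepcopy(root)
    kinds = ["update", "move", rng.choice(["insert", "delete"])]
    for k in range(n_edits):
        kind = rng.choice(kinds)
        elems = _all_elements(t)
        if kind == "update":
            el = rng.choice(elems)
            for a in el.attributes:
                if a.label == "w":
                    a.value = f"u{k}{rng.randint(10, 99)}"
        elif kind == "insert":
            # fresh values throughout: a value shared with an existing or
            # updated leaf would let the label-agnostic oracle merge the
            # insert with an unrelated relabel, invalidating the bound
            el = rng.choice(elems)
            child = XmlNode(kind="element", label=rng.choice(["a", "b", "c", "d"]))
            child.attributes = [
                XmlNode(kind="attribute", label="id", value=f"new{k}"),
                XmlNode(kind="attribute", label="w", value=f"nw{k}{rng.randint(10, 99)}"),
            ]
            el.children.insert(rng.randrange(len(el.children) + 1), child)
        elif kind == "move":
            movable = [e for e in elems if e is not t]
            if not movable:
                continue
            el = rng.choice(movable)
            inside = set(map(id, _all_elements(el)))
            targets = [e for e in elems if id(e) not in inside and id(e) != id(el)]
            if not targets:
                continue
            parent = next(p for p in elems for c in p.children if c is el)
            parent.children.remove(el)
            dst = rng.choice(targets)
            dst.children.insert(rng.randrange(len(dst.children) + 1), el)
        else:
            leaves = [
                (p, c) for p in elems for c in p.element_children()
                if not c.children
            ]
            if leaves:
                p, c = rng.choice(leaves)
                p.children.remove(c)
    return t


def _all_elements(root: XmlNode) -> list[XmlNode]:
    out = [root]
    for c in root.children:
        if c.kind == "element":
            out.extend(_all_elements(c))
    return out
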