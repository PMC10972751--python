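"""Rooted/unrooted tree container used throughout the package.

Branch lengths are expected substitutions per site unless a tree is dated, in
which case node ``age`` is in millions of years (Ma) and the tree is
ultrametric.  Internal nodes may carry a ``kind`` annotation (``"speciation"``
or ``"duplication"``), an ``event`` id (e.g. ``"1R"``) and a bootstrap
``support`` in [0, 100].
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional

import dendropy


class Node:
    __slots__ = (
        "name",
        "length",
        "children",
        "parent",
        "age",
        "kind",
        "event",
        "support",
    )

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.age: Optional[float] = None
        self.kind: Optional[str] = None
        self.event: Optional[str] = None
        self.support: Optional[float] = None

    # -- construction -----------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    # -- queries -----------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Optional["Node"]:
        for n in self.postorder():
            if n.name == name:
                return n
        return None

    def mrca(self, names) -> "Node":
        """Most recent common ancestor of the named tips."""
        want = set(names)
        best = None
        for node in self.postorder():
            if want <= set(node.leaf_names()):
                best = node
                break
        if best is None:
            raise ValueError(f"tips {sorted(want)} not all present")
        return best

    def copy(self) -> "Node":
        new = Node(self.name, self.length)
        new.age, new.kind, new.event, new.support = (
            self.age,
            self.kind,
            self.event,
            self.support,
        )
        for c in self.children:
            new.add_child(c.copy())
        return new

    # -- topology edits ----------------------------------------------------
    def suppress_unifurcations(self) -> "Node":
        """Remove nodes with a single child (merging branch lengths).

        Returns the (possibly new) root.
        """
        root = self
        while len(root.children) == 1:
            child = root.children[0]
            child.parent = None
            child.length += root.length
            root = child
        for node in list(root.postorder()):
            if node is root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
        return root

    def root_with_outgroup(self, outgroup_names) -> "Node":
        """Return a copy rooted on the branch leading to the outgroup clade."""
        tree = self.copy()
        out = set(outgroup_names)
        if out == set(tree.leaf_names()):
            raise ValueError("outgroup covers the whole tree")
        # locate the edge whose subtree is exactly the outgroup (or reroot on
        # the single outgroup tip's edge)
        target = None
        for node in tree.postorder():
            if node is tree:
                continue
            if set(node.leaf_names()) == out:
                target = node
                break
        if target is None:
            raise ValueError("outgroup is not a clade of this tree")
        return reroot_on_edge(tree, target)

    # -- serialization -----------------------------------------------------
    def newick(self, annotations: bool = False) -> str:
        buf = io.StringIO()
        _write_newick(self, buf, annotations)
        buf.write(";")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.newick()}>"


def _write_newick(node: Node, buf: io.StringIO, annotations: bool) -> None:
    if node.children:
        buf.write("(")
        for i, c in enumerate(node.children):
            if i:
                buf.write(",")
            _write_newick(c, buf, annotations)
        buf.write(")")
    if node.name:
        buf.write(str(node.name))
    elif node.children and node.support is not None:
        buf.write(f"{node.support:g}")
    if annotations:
        parts = []
        if node.kind:
            parts.append(f"type={node.kind}")
        if node.event:
            parts.append(f"event={node.event}")
        if node.age is not None:
            parts.append(f"age={node.age:g}")
        if node.support is not None:
            parts.append(f"support={node.support:g}")
        if parts:
            buf.write("[&" + ",".join(parts) + "]")
    if node.parent is not None:
        buf.write(f":{node.length:.10g}")


def reroot_on_edge(tree: Node, target: Node, fraction: float = 0.5) -> Node:
    """Reroot so the root splits the edge above ``target``."""
    if target.parent is None:
        raise ValueError("cannot reroot on the root's own edge")
    new_root = Node()
    old_parent = target.parent
    old_parent.remove_child(target)
    dist = target.length
    target.length = dist * fraction
    # reverse the path from old_parent up to the old root
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = node.parent
    lengths = [n.length for n in path]
    for i in range(len(path) - 1):
        child, parent = path[i], path[i + 1]
        parent.remove_child(child)
        child.add_child(parent)
        parent.length = lengths[i]
    new_root.add_child(target)
    new_root.add_child(old_parent)
    old_parent.length = dist * (1.0 - fraction)
    root = new_root
    # the old root may now be a unifurcation
    return root.suppress_unifurcations() if _has_unifurcation(root) else root


def _has_unifurcation(root: Node) -> bool:
    return any(len(n.children) == 1 for n in root.postorder())


def from_newick(text: str) -> Node:
    """Parse a newick string (via dendropy) into a :class:`Node` tree."""
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    return _convert(dtree.seed_node)


def _convert(dnode) -> Node:
    node = Node(
        name=dnode.taxon.label if dnode.taxon else dnode.label,
        length=dnode.edge.length or 0.0,
    )
    for c in dnode.child_nodes():
        node.add_child(_convert(c))
    if node.children and node.name is not None:
        # internal labels written by newick() are supports
        try:
            node.support = float(node.name)
            node.name = None
        except ValueError:
            pass
    return node


def bipartitions(tree: Node) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of tip names."""
    all_names = frozenset(tree.leaf_names())
    out = set()
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_names - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return out


def robinson_foulds(a: Node, b: Node) -> int:
    ba, bb = bipartitions(a), bipartitions(b)
    return len(ba ^ bb)


def patristic_distances(tree: Node, names: list[str]):
    """Pairwise path-length (patristic) distance matrix over named tips."""
    import numpy as np

    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    D = np.zeros((n, n))
    # distances from each node to tips below it, accumulated upward
    below: dict[int, dict[int, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {idx[node.name]: 0.0}
            continue
        merged: dict[int, float] = {}
        kids = [
            {k: v + c.length for k, v in below[id(c)].items()}
            for c in node.children
        ]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i, di in kids[a].items():
                    for j, dj in kids[b].items():
                        D[i, j] = D[j, i] = di + dj
            merged.update(kids[a])
        merged.update(kids[-1])
        below[id(node)] = merged
    return D


def set_ages_from_lengths(tree: Node) -> None:
    """For an ultrametric tree with lengths in time units, fill node ages."""
    depth: dict[int, float] = {id(tree): 0.0}
    maxd = 0.0
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + node.length
        maxd = max(maxd, depth[id(node)])
    for node in tree.postorder():
        node.age = maxd - depth[id(node)]


def set_lengths_from_ages(tree: Node, rate: float = 1.0) -> None:
    for node in tree.postorder():
        if node.parent is not None:
            node.length = (node.parent.age - node.age) * rate
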