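"""Rooted trees with mutation-count branch lengths.

A deliberately small tree structure: branches carry a length (a mutation
count, later a coverage-corrected float), an optional list of mutation
identifiers, a bootstrap support for internal splits, and a node time in
years once a tree has been scaled.  The root's own ``length`` is the root
branch (the edge above the first split) — mutations shared by every colony
live there.

Newick I/O goes through dendropy so externally built trees can be dropped
in; the in-memory structure stays minimal because the time-scaling and
mutation-mapping algorithms manipulate it directly.
"""

from __future__ import annotations

import io
import itertools
from typing import Callable, Iterator, Optional

import dendropy


class Node:
    __slots__ = (
        "name",
        "length",
        "children",
        "parent",
        "mutations",
        "support",
        "time",
        "flags",
    )

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.mutations: list = []
        self.support: Optional[float] = None
        self.time: Optional[float] = None
        self.flags: set[str] = set()

    # -- structure ---------------------------------------------------------

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or 'internal'} len={self.length:g}>"


class Tree:
    """A rooted tree; ``root.length`` is the branch above the root."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        return [
            n
            for n in self.preorder()
            if n.children and (include_root or n is not self.root)
        ]

    # -- queries -----------------------------------------------------------

    def find(self, name: str) -> Node:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def clade_tips(self, node: Node) -> frozenset[str]:
        return frozenset(t.name for t in self._subtree_tips(node))

    @staticmethod
    def _subtree_tips(node: Node) -> list[Node]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            stack.extend(n.children)
        return out

    def ancestors(self, node: Node, include_self: bool = False) -> list[Node]:
        """Nodes on the path from ``node`` to the root (rootmost last)."""
        out = [node] if include_self else []
        n = node.parent
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    def mrca(self, names) -> Node:
        names = list(names)
        node = self.find(names[0])
        anc = [node] + self.ancestors(node)
        anc_set = {id(a): i for i, a in enumerate(anc)}
        best = 0
        for nm in names[1:]:
            n = self.find(nm)
            while id(n) not in anc_set:
                n = n.parent
                if n is None:
                    raise ValueError("tips do not share a root")
            best = max(best, anc_set[id(n)])
        return anc[best]

    def distance_to_root(self, node: Node, attr: str = "length") -> float:
        """Sum of branch lengths from the top of the root branch to ``node``."""
        total = 0.0
        n = node
        while n is not None:
            total += getattr(n, attr)
            n = n.parent
        return total

    def max_tip_distance(self) -> float:
        return max(self.distance_to_root(t) for t in self.tips())

    # -- editing -----------------------------------------------------------

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            c = Node(node.name, node.length)
            c.mutations = list(node.mutations)
            c.support = node.support
            c.time = node.time
            c.flags = set(node.flags)
            for child in node.children:
                c.add_child(_copy(child))
            return c

        return Tree(_copy(self.root))

    # -- I/O ---------------------------------------------------------------

    def to_newick(self, lengths: str = "length", digits: int = 6) -> str:
        def fmt(node: Node) -> str:
            val = getattr(node, lengths)
            if lengths == "time":
                # emit branch spans, not absolute times
                pval = getattr(node.parent, "time", 0.0) if node.parent else 0.0
                val = (val or 0.0) - (pval or 0.0)
            label = node.name or ""
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner}){label}"
            return f"{label}:{0.0 if val is None else round(val, digits):g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, source: str) -> "Tree":
        """Parse a Newick string or file path (via dendropy)."""
        kwargs = dict(schema="newick", preserve_underscores=True)
        if "\n" in source or source.strip().endswith(";") or "(" in source:
            dtree = dendropy.Tree.get(data=source, **kwargs)
        else:
            dtree = dendropy.Tree.get(path=source, **kwargs)

        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name, length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))


def pairwise_shared_length(tree: Tree, name_a: str, name_b: str) -> float:
    """Total branch length on the common root path of two tips.

    On a mutation-count tree this is the number of somatic mutations the two
    colonies share through their common ancestry (the root branch included).
    """
    mrca = tree.mrca([name_a, name_b])
    return sum(n.length for n in tree.ancestors(mrca, include_self=True))


def median_pairwise_shared(tree: Tree, names=None) -> float:
    """Median pairwise shared-mutation count over the given tips."""
    import numpy as np

    names = list(names) if names is not None else tree.tip_names()
    vals = [
        pairwise_shared_length(tree, a, b)
        for a, b in itertools.combinations(names, 2)
    ]
    return float(np.median(vals))
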