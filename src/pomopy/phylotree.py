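"""Lightweight rooted trees with branch lengths.

The inference engine, branch-length optimizer and simulator all need cheap
mutation and traversal, so trees are plain linked nodes.  Newick parsing
goes through dendropy (see :mod:`pomopy.io_formats`); this module only
keeps the in-memory structure and a canonical Newick writer.

Branch lengths are in normalized event units (expected mutation-plus-drift
events per site); under reversible models root placement does not affect
the likelihood, so rooted storage carries unrooted semantics.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Node", "PhyloTree"]


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list["Node"] = []
        self.parent: "Node | None" = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r}, {self.length})"


class PhyloTree:
    """Rooted tree over named leaves."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        from . import io_formats

        return io_formats.parse_newick(newick)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    # -- traversal -----------------------------------------------------------

    def postorder(self):
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> list[Node]:
        """Child nodes of edges whose both endpoints are internal."""
        return [
            n
            for n in self.postorder()
            if not n.is_leaf and n.parent is not None
        ]

    # -- properties ----------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def height(self) -> float:
        """Maximum root-to-tip path length."""

        def depth(node: Node, acc: float) -> float:
            if node.is_leaf:
                return acc
            return max(depth(c, acc + c.length) for c in node.children)

        return depth(self.root, 0.0)

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def branch_lengths(self) -> np.ndarray:
        return np.array(
            [n.length for n in self.postorder() if n.parent is not None]
        )

    def scale(self, factor: float) -> "PhyloTree":
        for n in self.postorder():
            if n.parent is not None:
                n.length *= factor
        return self

    # -- unrooting -----------------------------------------------------------

    def unroot(self) -> "PhyloTree":
        """Collapse a degree-2 root in place, merging its two edges."""
        if len(self.root.children) != 2:
            return self
        a, b = self.root.children
        donor = a if not a.is_leaf else b
        if donor.is_leaf:  # two-leaf tree: nothing to collapse
            return self
        other = b if donor is a else a
        other.length += donor.length
        self.root.children = [other]
        other.parent = self.root
        for c in donor.children:
            self.root.add_child(c)
        return self

    # -- splits --------------------------------------------------------------

    def splits(self, with_lengths: bool = False, include_trivial: bool = False):
        """Bipartitions of the leaf set under unrooted semantics.

        Each split is canonicalized as the frozenset of leaf names on the
        side *not* containing the lexicographically smallest leaf.  The two
        edges incident to a degree-2 root induce the same bipartition and
        their lengths are summed (one unrooted branch).  Trivial (pendant)
        splits are excluded unless ``include_trivial`` is set.  Returns a
        ``dict`` split -> length when ``with_lengths``, else a ``set``.
        """
        names = sorted(self.leaf_names())
        ref = names[0]
        full = frozenset(names)
        below: dict[int, frozenset] = {}
        result: dict[frozenset, float] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset(
                    itertools.chain.from_iterable(below[id(c)] for c in node.children)
                )
            if node.parent is None:
                continue
            side = below[id(node)]
            if ref in side:
                side = full - side
            if not include_trivial and not 2 <= len(side) <= len(names) - 2:
                continue
            result[side] = result.get(side, 0.0) + node.length
        return result if with_lengths else set(result)

    # -- serialization -------------------------------------------------------

    def newick(self, digits: int = 12) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    body += node.name
            if node.parent is not None:
                body += ":" + np.format_float_positional(
                    node.length, precision=digits, unique=True, trim="0"
                )
            return body

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.newick(digits=4)})"
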