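"""Unrooted leaf-labeled phylogenetic trees.

Trees are stored as undirected adjacency structures: internal nodes are
unlabeled and, on binary trees, have degree 3 (polytomies, produced by
zero-length-branch collapsing, have higher degree).  Parsimony length is
invariant under the choice of display root, so rooting — on the outgroup or
anywhere else — is a presentation concern handled only at Newick export.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

__all__ = ["Node", "PhyloTree"]


class Node:
    """A tree vertex; leaves carry a taxon label, internal nodes ``None``."""

    __slots__ = ("label", "nbrs")

    def __init__(self, label: str | None = None):
        self.label = label
        self.nbrs: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    @property
    def degree(self) -> int:
        return len(self.nbrs)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, deg={self.degree})"


def _connect(u: Node, v: Node) -> None:
    u.nbrs.append(v)
    v.nbrs.append(u)


def _disconnect(u: Node, v: Node) -> None:
    u.nbrs.remove(v)
    v.nbrs.remove(u)


class PhyloTree:
    """An unrooted tree over a fixed set of uniquely labeled leaves."""

    def __init__(self, leaves: dict[str, Node]):
        if not leaves:
            raise ValueError("tree must have at least one leaf")
        self.leaf_map = leaves

    # -- construction -----------------------------------------------------

    @classmethod
    def star(cls, labels: Iterable[str]) -> "PhyloTree":
        """Single internal node joined to every leaf (fully unresolved)."""
        labels = list(labels)
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")
        center = Node()
        leaves = {}
        for lab in labels:
            leaf = Node(lab)
            _connect(center, leaf)
            leaves[lab] = leaf
        return cls(leaves)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
        conv: dict[object, Node] = {}
        leaves: dict[str, Node] = {}
        for dnode in dtree.preorder_node_iter():
            if dnode.is_leaf():
                lab = dnode.taxon.label if dnode.taxon else dnode.label
                node = Node(lab)
                if lab in leaves:
                    raise ValueError(f"duplicate leaf label {lab!r}")
                leaves[lab] = node
            else:
                node = Node()
            conv[dnode] = node
            if dnode.parent_node is not None:
                _connect(conv[dnode.parent_node], node)
        tree = cls(leaves)
        # a rooted Newick string has a degree<=2 root; unrooted semantics
        root = conv[dtree.seed_node]
        if not root.is_leaf and root.degree <= 2:
            tree._suppress(root)
        return tree

    def copy(self) -> "PhyloTree":
        tree, _ = self.copy_with_map()
        return tree

    def copy_with_map(self) -> tuple["PhyloTree", dict[Node, Node]]:
        mapping: dict[Node, Node] = {}
        for node in self.nodes():
            mapping[node] = Node(node.label)
        for node in self.nodes():
            mapping[node].nbrs = [mapping[n] for n in node.nbrs]
        return PhyloTree({lab: mapping[n] for lab, n in self.leaf_map.items()}), mapping

    # -- inspection -------------------------------------------------------

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.leaf_map)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_map)

    def nodes(self) -> list[Node]:
        """All nodes, in a deterministic depth-first order."""
        start = self.leaf_map[min(self.leaf_map)]
        seen = {start}
        order = [start]
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in node.nbrs:
                if nbr not in seen:
                    seen.add(nbr)
                    order.append(nbr)
                    stack.append(nbr)
        return order

    def edges(self) -> list[tuple[Node, Node]]:
        out = []
        for node, parent in self.traverse():
            if parent is not None:
                out.append((parent, node))
        return out

    def internal_edges(self) -> list[tuple[Node, Node]]:
        return [(u, v) for u, v in self.edges()
                if not u.is_leaf and not v.is_leaf]

    def is_binary(self) -> bool:
        return all(n.degree == 3 for n in self.nodes() if not n.is_leaf) \
            and self.n_leaves >= 3

    def traverse(self, root: Node | None = None) -> list[tuple[Node, Node | None]]:
        """Preorder (node, parent) pairs from ``root`` (default: min-label leaf)."""
        if root is None:
            root = self.leaf_map[min(self.leaf_map)]
        order = [(root, None)]
        stack = [(root, None)]
        while stack:
            node, parent = stack.pop()
            for nbr in node.nbrs:
                if nbr is not parent:
                    order.append((nbr, node))
                    stack.append((nbr, node))
        return order

    def postorder(self, root: Node | None = None) -> list[tuple[Node, Node | None]]:
        return list(reversed(self.traverse(root)))

    # -- identity ---------------------------------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side that excludes
        the lexicographically smallest leaf label."""
        ref = min(self.leaf_map)
        below: dict[Node, frozenset[str]] = {}
        out = set()
        n = self.n_leaves
        for node, parent in self.postorder():
            if node.is_leaf:
                below[node] = frozenset((node.label,))
            else:
                below[node] = frozenset().union(
                    *(below[c] for c in node.nbrs if c is not parent))
            if parent is not None and 2 <= len(below[node]) <= n - 2:
                out.add(below[node])
        return frozenset(out)

    def topology_key(self) -> tuple[frozenset[str], frozenset[frozenset[str]]]:
        """Hashable identity: equal iff same leaves and same splits."""
        return (self.labels, self.bipartitions())

    # -- surgery ----------------------------------------------------------

    def _suppress(self, node: Node) -> None:
        """Remove a degree-2 unlabeled node, fusing its two incident edges."""
        if node.is_leaf or node.degree != 2:
            raise ValueError("can only suppress an internal degree-2 node")
        a, b = node.nbrs
        _disconnect(node, a)
        _disconnect(node, b)
        _connect(a, b)

    def prune_leaf(self, label: str) -> None:
        """Remove a leaf in place, suppressing the degree-2 node left behind."""
        if label not in self.leaf_map:
            raise KeyError(f"no leaf labeled {label!r}")
        leaf = self.leaf_map.pop(label)
        (nbr,) = leaf.nbrs
        _disconnect(leaf, nbr)
        if not nbr.is_leaf:
            if nbr.degree == 2:
                self._suppress(nbr)
            elif nbr.degree == 1:
                # 2-leaf tree degenerating; splice out the bare internal node
                (other,) = nbr.nbrs
                _disconnect(nbr, other)

    def restricted(self, keep: Iterable[str]) -> "PhyloTree":
        """Copy of the tree induced on a subset of the leaves."""
        keep = set(keep)
        missing = keep - self.labels
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        tree = self.copy()
        for lab in sorted(self.labels - keep):
            tree.prune_leaf(lab)
        return tree

    # -- Newick -----------------------------------------------------------

    @staticmethod
    def _quote(label: str) -> str:
        if any(c in label for c in " ()[]{}:;,'\t\n"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def newick(self, outgroup: str | None = None) -> str:
        """Canonical Newick string: children are ordered by their smallest
        leaf label, so topologically equal trees serialize identically.
        With ``outgroup`` the tree is displayed rooted on that leaf's
        pendant edge (scoring is unaffected by rooting)."""

        def sub(node: Node, parent: Node) -> tuple[str, str]:
            """Returns (min leaf label in subtree, newick fragment)."""
            if node.is_leaf:
                return node.label, self._quote(node.label)
            parts = sorted(sub(c, node) for c in node.nbrs if c is not parent)
            return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

        if self.n_leaves == 1:
            (lab,) = self.labels
            return self._quote(lab) + ";"
        if outgroup is not None:
            if outgroup not in self.leaf_map:
                raise KeyError(f"outgroup {outgroup!r} not in tree")
            og = self.leaf_map[outgroup]
            (nbr,) = og.nbrs
            return f"({self._quote(outgroup)},{sub(nbr, og)[1]});"
        # root the string at the neighbor of the smallest-label leaf
        anchor = self.leaf_map[min(self.leaf_map)]
        nbr = anchor.nbrs[0]
        if nbr.is_leaf:
            parts = [self._quote(anchor.label), self._quote(nbr.label)]
        else:
            parts = [self._quote(anchor.label)] + \
                [p[1] for p in sorted(sub(c, nbr)
                                      for c in nbr.nbrs if c is not anchor)]
        return "(" + ",".join(parts) + ");"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_leaves} leaves)"


# re-exported for internal modules doing tree surgery
connect = _connect
disconnect = _disconnect
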