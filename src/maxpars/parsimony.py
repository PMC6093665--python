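"""Equally weighted parsimony scoring of trees on character matrices.

Each character is optimized by a vectorized minimum-cost dynamic program
over the state line 0..9 (a Sankoff-style pass).  With unit costs between
distinct states this reproduces Fitch optimization for unordered
(non-additive) characters; with cost |i-j| it reproduces additive (Farris)
optimization for ordered characters.  Unlike the classical set-based
passes, the dynamic program is exact on multifurcating trees as well, which
rule-1 collapsed trees require.  Missing cells ('?'/'-') are maximally
ambiguous and never add cost.

The same machinery answers the per-edge question used for zero-length-
branch collapsing: the minimum number of changes assigned to an internal
edge over *all* most-parsimonious reconstructions of each character.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import CharacterMatrix, StateSet, normalize_label
from .tree import Node, PhyloTree

__all__ = ["LengthBreakdown", "ParsimonyScorer", "character_length",
           "tree_length", "min_branch_length"]

INF = 1 << 20


@dataclass(frozen=True)
class LengthBreakdown:
    """Per-character step counts and their total (the tree length)."""

    per_char: tuple[int, ...]

    @property
    def total(self) -> int:
        return int(sum(self.per_char))


class ParsimonyScorer:
    """Scoring engine bound to one matrix; reusable across many trees."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.nchar = matrix.nchar
        self.nstates = max(2, max(matrix.alphabet_per_char, default=1) + 1)
        self.ordered_mask = np.asarray(matrix.ordered, dtype=bool)
        self._leaf_cost = {}
        for label, row in zip(matrix.taxa, matrix.cells):
            arr = np.full((self.nchar, self.nstates), INF, dtype=np.int64)
            for j, cell in enumerate(row):
                if cell.is_missing:
                    arr[j, :] = 0
                else:
                    arr[j, list(cell.states)] = 0
            self._leaf_cost[normalize_label(label)] = arr
        S = self.nstates
        line = np.arange(S)
        self._w_ord = np.abs(line[:, None] - line[None, :])
        self._w_unord = (line[:, None] != line[None, :]).astype(np.int64)
        # per-character (S, S) substitution-cost stack, for edge queries
        self._w_per_char = np.where(self.ordered_mask[:, None, None],
                                    self._w_ord[None], self._w_unord[None])

    def leaf_cost(self, label: str) -> np.ndarray:
        try:
            return self._leaf_cost[normalize_label(label)]
        except KeyError:
            raise KeyError(f"leaf {label!r} has no row in the matrix") from None

    # -- core DP ----------------------------------------------------------

    def transform(self, cost: np.ndarray) -> np.ndarray:
        """Child-edge contribution: ``g[s] = min_t cost[t] + w(s, t)`` with
        the per-character cost rule, vectorized over leading axes."""
        unord = np.minimum(cost, cost.min(axis=-1, keepdims=True) + 1)
        ordd = cost.copy()
        for s in range(1, self.nstates):
            np.minimum(ordd[..., s], ordd[..., s - 1] + 1, out=ordd[..., s])
        for s in range(self.nstates - 2, -1, -1):
            np.minimum(ordd[..., s], ordd[..., s + 1] + 1, out=ordd[..., s])
        mask = self.ordered_mask
        if cost.ndim == 3:
            mask = mask[None, :, None]
        else:
            mask = mask[:, None]
        return np.where(mask, ordd, unord)

    def down_from_post(self, post: list) -> dict:
        """Subtree cost arrays for a postorder list of (node, parent)."""
        down: dict[Node, np.ndarray] = {}
        for node, parent in post:
            if node.is_leaf:
                a = self.leaf_cost(node.label).copy()
            else:
                a = np.zeros((self.nchar, self.nstates), dtype=np.int64)
            for child in node.nbrs:
                if child is not parent:
                    a += self.transform(down[child])
            down[node] = a
        return down

    def updown_from_post(self, post: list) -> tuple[dict, dict]:
        """Directed cost arrays for both orientations of every edge.

        ``down[v]`` covers the subtree below v; ``up[v]`` covers the
        complement component, seen from v's parent.
        """
        down = self.down_from_post(post)
        parent_of = {n: p for n, p in post}
        tdown = {n: self.transform(down[n]) for n, p in post if p is not None}
        up: dict[Node, np.ndarray] = {}
        for node, parent in reversed(post):       # preorder
            if parent is None:
                continue
            if parent.is_leaf:
                base = self.leaf_cost(parent.label).copy()
            else:
                base = np.zeros((self.nchar, self.nstates), dtype=np.int64)
            for sib in parent.nbrs:
                if sib is node or sib is parent_of[parent]:
                    continue
                base += tdown[sib]
            if parent_of[parent] is not None:
                base += self.transform(up[parent])
            up[node] = base
        return down, up

    def down_arrays(self, tree: PhyloTree,
                    root: Node | None = None) -> tuple[list, dict]:
        """Postorder subtree cost arrays; returns (postorder, arrays)."""
        post = tree.postorder(root)
        return post, self.down_from_post(post)

    def per_char_lengths(self, tree: PhyloTree, check: bool = True) -> np.ndarray:
        if check:
            self._check_labels(tree)
        post, down = self.down_arrays(tree)
        root = post[-1][0]
        return down[root].min(axis=1)

    def tree_length(self, tree: PhyloTree, check: bool = True) -> int:
        return int(self.per_char_lengths(tree, check=check).sum())

    def breakdown(self, tree: PhyloTree) -> LengthBreakdown:
        return LengthBreakdown(tuple(int(x) for x in self.per_char_lengths(tree)))

    def _check_labels(self, tree: PhyloTree) -> None:
        want = set(self._leaf_cost)
        got = {normalize_label(t) for t in tree.labels}
        if want != got:
            raise KeyError(
                f"tree/matrix leaf sets differ: only-in-matrix="
                f"{sorted(want - got)} only-in-tree={sorted(got - want)}")

    # -- per-edge queries -------------------------------------------------

    def edge_min_lengths(self, tree: PhyloTree) -> dict[frozenset, int]:
        """For every internal edge, the minimum number of changes assigned
        to it over all most-parsimonious reconstructions (summed over
        characters)."""
        self._check_labels(tree)
        post = tree.postorder()
        down, up = self.updown_from_post(post)
        result: dict[frozenset, int] = {}
        for node, parent in post:
            if parent is None or node.is_leaf or parent.is_leaf:
                continue
            D, U = down[node], up[node]
            total = U[:, :, None] + self._w_per_char + D[:, None, :]
            lc = total.min(axis=(1, 2))
            on_opt = total == lc[:, None, None]
            minw = np.where(on_opt, self._w_per_char, INF).min(axis=(1, 2))
            result[frozenset((node, parent))] = int(minw.sum())
        return result


# ---------------------------------------------------------------------------
# module-level conveniences matching the pipeline's vocabulary
# ---------------------------------------------------------------------------

def character_length(tree: PhyloTree, column: dict[str, StateSet],
                     ordered: bool = False) -> int:
    """Steps required by a single character on a tree."""
    taxa = sorted(column)
    matrix = CharacterMatrix(taxa, [[column[t]] for t in taxa], [ordered])
    return ParsimonyScorer(matrix).tree_length(tree)


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> LengthBreakdown:
    """Per-character and total parsimony length of a tree."""
    return ParsimonyScorer(matrix).breakdown(tree)


def min_branch_length(tree: PhyloTree, matrix: CharacterMatrix,
                      edge: tuple[Node, Node]) -> int:
    """Minimum changes forced onto an internal edge across all
    most-parsimonious reconstructions; terminal edges are rejected
    (they are never collapsed)."""
    u, v = edge
    if u.is_leaf or v.is_leaf:
        raise ValueError("min branch length is defined for internal edges only")
    lengths = ParsimonyScorer(matrix).edge_min_lengths(tree)
    try:
        return lengths[frozenset((u, v))]
    except KeyError:
        raise ValueError("edge does not belong to the tree") from None
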