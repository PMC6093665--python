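"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized engine: scoring is a
plain per-character recursion with explicit cost dictionaries, and the
minimum-edge-change oracle enumerates complete internal state assignments.
"""

from __future__ import annotations

import itertools
import math

from maxpars.matrix import CharacterMatrix
from maxpars.tree import Node, PhyloTree


def _allowed(cell, n_states: int) -> set[int]:
    if cell.is_missing:
        return set(range(n_states))
    return set(cell.states)


def _w(a: int, b: int, ordered: bool) -> int:
    return abs(a - b) if ordered else (0 if a == b else 1)


def sankoff_column_score(tree: PhyloTree, column: dict, ordered: bool,
                         n_states: int = 10) -> int:
    """Minimum changes for one character by naive recursive Sankoff DP."""

    def rec(node: Node, parent: Node | None) -> list[float]:
        if node.is_leaf:
            allowed = _allowed(column[node.label], n_states)
            cost = [0.0 if s in allowed else math.inf
                    for s in range(n_states)]
        else:
            cost = [0.0] * n_states
        for child in node.nbrs:
            if child is parent:
                continue
            ccost = rec(child, node)
            for s in range(n_states):
                cost[s] += min(ccost[t] + _w(s, t, ordered)
                               for t in range(n_states))
        return cost

    root = tree.leaf_map[min(tree.leaf_map)]
    return int(min(rec(root, None)))


def sankoff_matrix_score(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    total = 0
    for j in range(matrix.nchar):
        n_states = max(2, matrix.max_state(j) + 1)
        total += sankoff_column_score(tree, matrix.column(j),
                                      matrix.ordered[j], n_states)
    return total


def min_edge_changes_by_enumeration(tree: PhyloTree, column: dict,
                                    ordered: bool, edge, n_states: int) -> int:
    """Minimum changes on one edge over all optimal full state assignments,
    by enumerating every assignment of states to internal nodes."""
    internals = [n for n in tree.nodes() if not n.is_leaf]
    leaves = [n for n in tree.nodes() if n.is_leaf]
    edges = tree.edges()
    best_total = math.inf
    best_edge = math.inf
    eset = frozenset(edge)
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        state = dict(zip(internals, assign))
        total = 0.0
        for leaf in leaves:
            allowed = _allowed(column[leaf.label], n_states)
            # leaf may take any allowed state; choose the cheapest
            (nbr,) = leaf.nbrs
            total += min(_w(s, state[nbr], ordered) for s in allowed)
        on_edge = 0
        for u, v in edges:
            if u.is_leaf or v.is_leaf:
                continue
            w = _w(state[u], state[v], ordered)
            total += w
            if frozenset((u, v)) == eset:
                on_edge = w
        if total < best_total:
            best_total, best_edge = total, on_edge
        elif total == best_total:
            best_edge = min(best_edge, on_edge)
    return int(best_edge)


def is_tbr_neighbor(t1: PhyloTree, t2: PhyloTree) -> bool:
    """TBR-distance-1 characterization: some edge of t1 splits the leaves
    into (A, B) such that t2 also displays the split A|B (automatic when
    either side is a single leaf: the reconnecting edge of the move) and
    the two trees agree when restricted to A and to B."""
    if t1.topology_key() == t2.topology_key():
        return False
    labels = t1.labels
    ref = min(labels)

    def canon(side):
        return side if ref not in side else labels - side

    below = {}
    for node, parent in t1.postorder():
        if node.is_leaf:
            below[node] = frozenset((node.label,))
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.nbrs if c is not parent))
    sides = {below[n] for n, p in t1.postorder() if p is not None}
    t2_splits = t2.bipartitions()
    for a in sides:
        b = labels - a
        if not a or not b:
            continue
        if len(a) >= 2 and len(b) >= 2 and canon(a) not in t2_splits:
            continue
        ok = True
        for part in (a, b):
            if len(part) >= 4:
                if t1.restricted(part).topology_key() != \
                        t2.restricted(part).topology_key():
                    ok = False
                    break
        if ok:
            return True
    return False
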