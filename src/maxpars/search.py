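"""Heuristic and exhaustive search for most-parsimonious trees.

The heuristic protocol mirrors TNT's "traditional search": independent
replicates, each building a Wagner starting tree by random-sequence
stepwise addition and refining it by TBR branch swapping while holding a
fixed number of equally short trees, followed by a final TBR round over the
pooled buffer with the hold limit lifted.  Zero-length branches of the
resulting trees are collapsed (rule 1: an internal branch is deleted when
its minimum length over all most-parsimonious reconstructions is zero) and
the distinct collapsed topologies are returned.

TBR reconnections are scored without materializing neighbor trees: for each
bisection the engine computes edge-rooted cost arrays on both fragments,
after which every reconnection is a constant number of vectorized array
operations.  Neighbor trees are built only when accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import INF, ParsimonyScorer
from .tree import Node, PhyloTree, connect, disconnect

logger = logging.getLogger(__name__)

__all__ = ["SearchConfig", "TreeSet", "wagner_addition", "tbr_swap",
           "tbr_neighborhood", "heuristic_search", "collapse_zero_length",
           "exhaustive_search", "suboptimal_pool"]

MAX_EXHAUSTIVE_TAXA = 9


@dataclass
class SearchConfig:
    """Replication of the study protocol: 100 random-addition replicates,
    TBR, 10 trees held per replicate, rule-1 collapsing."""

    n_replicates: int = 100
    hold_per_replicate: int = 10
    max_trees: int = 10_000
    seed: int = 0
    collapse_rule: str = "rule1"
    final_swap: bool = True

    def __post_init__(self):
        if self.n_replicates < 1 or self.hold_per_replicate < 1:
            raise ValueError("n_replicates and hold_per_replicate must be >= 1")
        if self.collapse_rule != "rule1":
            raise ValueError(f"unsupported collapse rule {self.collapse_rule!r}")


@dataclass
class TreeSet:
    """Distinct equally parsimonious trees sharing one leaf set."""

    trees: list[PhyloTree]
    length: int | None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def topology_keys(self) -> set:
        return {t.topology_key() for t in self.trees}

    @staticmethod
    def dedup(trees: Iterable[PhyloTree]) -> list[PhyloTree]:
        seen, out = set(), []
        for t in trees:
            k = t.topology_key()
            if k not in seen:
                seen.add(k)
                out.append(t)
        return out


def _as_scorer(matrix) -> ParsimonyScorer:
    return matrix if isinstance(matrix, ParsimonyScorer) else ParsimonyScorer(matrix)


# ---------------------------------------------------------------------------
# fragment machinery shared by Wagner addition and TBR
# ---------------------------------------------------------------------------

def _postorder_from(start: Node) -> list[tuple[Node, Node | None]]:
    order = [(start, None)]
    stack = [(start, None)]
    while stack:
        node, parent = stack.pop()
        for nbr in node.nbrs:
            if nbr is not parent:
                order.append((nbr, node))
                stack.append((nbr, node))
    return list(reversed(order))


def _edge_rooted_arrays(scorer: ParsimonyScorer, start: Node):
    """Attachment points of a fragment with, for each, the cost array of the
    fragment rooted at an imaginary node subdividing that edge.

    Returns ``(edges, stack)`` where an isolated leaf contributes the single
    pseudo-edge ``(leaf, None)`` whose array is the leaf's own cost.
    """
    post = _postorder_from(start)
    if len(post) == 1:
        return [(start, None)], scorer.leaf_cost(start.label)[None]
    down, up = scorer.updown_from_post(post)
    edges, stacks = [], []
    for node, parent in post:
        if parent is None:
            continue
        edges.append((parent, node))
        stacks.append(scorer.transform(down[node]) + scorer.transform(up[node]))
    return edges, np.stack(stacks)


def _copy_component(nodes: list[Node]) -> dict[Node, Node]:
    mapping = {n: Node(n.label) for n in nodes}
    for n in nodes:
        mapping[n].nbrs = [mapping[x] for x in n.nbrs]
    return mapping


def _component(start: Node) -> list[Node]:
    return [n for n, _ in _postorder_from(start)]


def _subdivide(u: Node, v: Node) -> Node:
    mid = Node()
    disconnect(u, v)
    connect(u, mid)
    connect(mid, v)
    return mid


def _tree_from_nodes(nodes: Iterable[Node]) -> PhyloTree:
    return PhyloTree({n.label: n for n in nodes if n.is_leaf})


# ---------------------------------------------------------------------------
# Wagner stepwise addition
# ---------------------------------------------------------------------------

def wagner_addition(matrix: CharacterMatrix,
                    addition_order: list[str] | None = None,
                    rng: np.random.Generator | None = None,
                    scorer: ParsimonyScorer | None = None) -> PhyloTree:
    """Build a binary starting tree by stepwise addition.

    Starting from the unique unrooted tree on the first three taxa, each
    remaining taxon (in the given order, or a random order drawn from
    ``rng``) is inserted on the branch that minimizes the increase in total
    length; ties are broken uniformly at random.
    """
    if matrix.ntax < 3:
        raise ValueError("Wagner addition requires at least 3 taxa")
    rng = rng if rng is not None else np.random.default_rng()
    scorer = scorer if scorer is not None else ParsimonyScorer(matrix)
    if addition_order is None:
        addition_order = [matrix.taxa[i]
                          for i in rng.permutation(matrix.ntax)]
    if set(addition_order) != set(matrix.taxa):
        raise ValueError("addition order must list every taxon exactly once")

    tree = PhyloTree.star(addition_order[:3])
    for label in addition_order[3:]:
        anchor = next(iter(tree.leaf_map.values()))
        edges, stack = _edge_rooted_arrays(scorer, anchor)
        tleaf = scorer.transform(scorer.leaf_cost(label))
        lengths = (stack + tleaf[None]).min(axis=2).sum(axis=1)
        best = lengths.min()
        choices = np.flatnonzero(lengths == best)
        pick = int(choices[rng.integers(len(choices))])
        u, v = edges[pick]
        mid = _subdivide(u, v)
        leaf = Node(label)
        connect(mid, leaf)
        tree.leaf_map[label] = leaf
    return tree


# ---------------------------------------------------------------------------
# TBR
# ---------------------------------------------------------------------------

def _tbr_bisections(tree: PhyloTree, scorer: ParsimonyScorer):
    """For every bisection of a binary tree: the cut tree's two fragments
    with their attachment edges and edge-rooted cost arrays."""
    base_nodes = tree.nodes()
    for u0, v0 in tree.edges():
        mapping = {n: Node(n.label) for n in base_nodes}
        for n in base_nodes:
            mapping[n].nbrs = [mapping[x] for x in n.nbrs]
        a, b = mapping[u0], mapping[v0]
        disconnect(a, b)
        for end in (a, b):
            if not end.is_leaf and end.degree == 2:
                x, y = end.nbrs
                disconnect(end, x)
                disconnect(end, y)
                connect(x, y)
                if end is a:
                    a = x
                else:
                    b = x
        ea, sa = _edge_rooted_arrays(scorer, a)
        eb, sb = _edge_rooted_arrays(scorer, b)
        yield (a, b, ea, sa, eb, sb)


def _materialize(a: Node, b: Node, edge_a, edge_b) -> PhyloTree:
    nodes = _component(a) + _component(b)
    m = _copy_component(nodes)

    def attach_point(edge):
        u, v = edge
        if v is None:          # isolated-leaf fragment
            return m[u]
        return _subdivide(m[u], m[v])

    x = attach_point(edge_a)
    y = attach_point(edge_b)
    connect(x, y)
    return _tree_from_nodes(m.values())


def tbr_swap(tree: PhyloTree, matrix, incumbent_length: int | float,
             ) -> Iterator[tuple[PhyloTree, int]]:
    """Stream the TBR neighbors of a binary tree whose length does not
    exceed ``incumbent_length`` (the original topology is never yielded).

    Every edge — internal or terminal — is cut; each fragment is rerooted
    on each of its edges and the fragments are rejoined in all ways.
    """
    if not tree.is_binary():
        raise ValueError("TBR swapping operates on binary trees")
    scorer = _as_scorer(matrix)
    own_key = tree.topology_key()
    for a, b, ea, sa, eb, sb in _tbr_bisections(tree, scorer):
        tb = scorer.transform(sb)
        lengths = (sa[:, None] + tb[None, :]).min(axis=3).sum(axis=2)
        for i, j in np.argwhere(lengths <= incumbent_length):
            nbr = _materialize(a, b, ea[i], eb[j])
            if nbr.topology_key() == own_key:
                continue
            yield nbr, int(lengths[i, j])


def tbr_neighborhood(tree: PhyloTree, matrix) -> list[PhyloTree]:
    """All distinct TBR neighbor topologies (any length)."""
    seen, out = set(), []
    for nbr, _ in tbr_swap(tree, matrix, INF):
        k = nbr.topology_key()
        if k not in seen:
            seen.add(k)
            out.append(nbr)
    return out


# ---------------------------------------------------------------------------
# swap-to-completion driver
# ---------------------------------------------------------------------------

def _swap_buffer(scorer: ParsimonyScorer, starts: list[PhyloTree],
                 hold: int, slack: int = 0):
    """TBR-swap every buffered tree to completion.

    With ``slack=0`` this is the classic search step: a strictly shorter
    neighbor replaces the whole buffer and swapping restarts from it; equal
    length neighbors are kept up to ``hold``.  With ``slack>0`` all trees
    within ``best+slack`` are retained (used for Bremer pools).
    Returns (best_length, list of (tree, length), complete_flag).
    """
    lengths = {id(t): scorer.tree_length(t) for t in starts}
    best = min(lengths.values())
    buffer, seen = [], set()
    for t in starts:
        if lengths[id(t)] <= best + slack:
            k = t.topology_key()
            if k not in seen:
                seen.add(k)
                buffer.append((t, lengths[id(t)]))
    complete = True
    i = 0
    while i < len(buffer):
        t, _ = buffer[i]
        restart = False
        for nbr, L in tbr_swap(t, scorer, best + slack):
            if L < best and slack == 0:
                best = L
                buffer = [(nbr, L)]
                seen = {nbr.topology_key()}
                restart = True
                break
            if L < best:        # slack > 0: rebase and drop the now-too-long
                best = L
                buffer = [(x, lx) for x, lx in buffer if lx <= best + slack]
                seen = {x.topology_key() for x, _ in buffer}
                i = 0           # re-swap survivors against the new bound
            k = nbr.topology_key()
            if k not in seen:
                if len(buffer) >= hold:
                    if slack > 0:
                        complete = False
                    continue
                seen.add(k)
                buffer.append((nbr, L))
        if restart:
            i = 0
        else:
            i += 1
    return best, buffer, complete


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

def collapse_zero_length(tree: PhyloTree, matrix) -> PhyloTree:
    """Rule-1 collapse: contract internal edges whose minimum length over
    all most-parsimonious reconstructions is zero.

    Edges are contracted one at a time (deterministic order: smallest
    bipartition first) and the minima recomputed, because two edges can
    each admit a change-free reconstruction without admitting one jointly
    — contracting them simultaneously could lengthen the tree.  One-at-a-
    time contraction provably preserves total length, and the fixed point
    makes the operation idempotent."""
    scorer = _as_scorer(matrix)
    new = tree.copy()
    while True:
        eml = scorer.edge_min_lengths(new)
        if not eml:
            return new
        post = new.postorder()
        below: dict[Node, frozenset] = {}
        for node, parent in post:
            if node.is_leaf:
                below[node] = frozenset((node.label,))
            else:
                below[node] = frozenset().union(
                    *(below[c] for c in node.nbrs if c is not parent))
        parent_of = {n: p for n, p in post}
        zero = []
        for edge, length in eml.items():
            if length > 0:
                continue
            u, v = tuple(edge)
            child = v if parent_of.get(v) is u else u
            zero.append((tuple(sorted(below[child])), edge))
        if not zero:
            return new
        _, edge = min(zero)
        u, v = tuple(edge)
        disconnect(u, v)
        for w in list(v.nbrs):
            disconnect(v, w)
            connect(u, w)


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def heuristic_search(matrix: CharacterMatrix,
                     config: SearchConfig | None = None) -> TreeSet:
    """Random-addition Wagner + TBR replicates, pooled final TBR round,
    rule-1 collapsing, and deduplication of the minimal-length trees."""
    config = config or SearchConfig()
    scorer = ParsimonyScorer(matrix)
    rng = np.random.default_rng(config.seed)
    pool: dict = {}
    global_best = None
    rep_stats = []
    complete = True
    for rep in range(config.n_replicates):
        order = [matrix.taxa[i] for i in rng.permutation(matrix.ntax)]
        start = wagner_addition(matrix, order, rng, scorer)
        best, buffer, _ = _swap_buffer(scorer, [start],
                                       hold=config.hold_per_replicate)
        rep_stats.append({"replicate": rep, "best_length": best,
                          "n_trees": len(buffer)})
        if global_best is None or best < global_best:
            global_best = best
            pool = {}
        if best == global_best:
            for t, _ in buffer:
                pool.setdefault(t.topology_key(), t)
                if len(pool) >= config.max_trees:
                    complete = False
                    break
    trees = list(pool.values())
    if config.final_swap:
        global_best, buffer, _ = _swap_buffer(scorer, trees,
                                              hold=config.max_trees)
        if len(buffer) >= config.max_trees:
            complete = False
        trees = [t for t, _ in buffer]
    collapsed = TreeSet.dedup(collapse_zero_length(t, scorer) for t in trees)
    if not complete:
        logger.warning("tree buffer cap (%d) reached; the MPT set may be "
                       "incomplete", config.max_trees)
    return TreeSet(
        trees=collapsed, length=int(global_best),
        provenance={"method": "heuristic", "seed": config.seed,
                    "n_replicates": config.n_replicates,
                    "hold_per_replicate": config.hold_per_replicate,
                    "complete": complete, "replicates": rep_stats,
                    "binary_trees": trees})


def _enumerate_topologies(labels: list[str]) -> Iterator[PhyloTree]:
    """All distinct unrooted binary topologies by recursive stepwise
    addition ((2n-5)!! of them)."""
    tree = PhyloTree.star(labels[:3])

    def rec(k: int) -> Iterator[PhyloTree]:
        if k == len(labels):
            yield tree.copy()
            return
        label = labels[k]
        for u, v in list(tree.edges()):
            mid = _subdivide(u, v)
            leaf = Node(label)
            connect(mid, leaf)
            tree.leaf_map[label] = leaf
            yield from rec(k + 1)
            tree.prune_leaf(label)

    yield from rec(3)


def exhaustive_search(matrix: CharacterMatrix) -> TreeSet:
    """Exact optimum set by complete enumeration (refused above
    9 taxa, where the topology count exceeds 2 million)."""
    if matrix.ntax > MAX_EXHAUSTIVE_TAXA:
        raise ValueError(
            f"exhaustive search supports at most {MAX_EXHAUSTIVE_TAXA} taxa "
            f"(got {matrix.ntax}); use heuristic_search")
    if matrix.ntax < 3:
        raise ValueError("need at least 3 taxa")
    scorer = ParsimonyScorer(matrix)
    best, best_trees = None, []
    n_eval = 0
    for tree in _enumerate_topologies(list(matrix.taxa)):
        n_eval += 1
        L = scorer.tree_length(tree)
        if best is None or L < best:
            best, best_trees = L, [tree]
        elif L == best:
            best_trees.append(tree)
    collapsed = TreeSet.dedup(collapse_zero_length(t, scorer)
                              for t in best_trees)
    return TreeSet(trees=collapsed, length=int(best),
                   provenance={"method": "exhaustive",
                               "n_topologies_evaluated": n_eval,
                               "binary_trees": best_trees})


def suboptimal_pool(matrix: CharacterMatrix, starts: Iterable[PhyloTree],
                    slack: int, cap: int = 10_000):
    """All distinct binary trees within ``best + slack`` reachable by TBR
    from the given optimal trees.  Returns (best_length,
    list of (tree, length), complete_flag); used for Bremer supports."""
    scorer = _as_scorer(matrix)
    if slack < 1:
        raise ValueError("slack must be >= 1")
    return _swap_buffer(scorer, list(starts), hold=cap, slack=slack)
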