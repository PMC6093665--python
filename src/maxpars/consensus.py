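"""Post-search pipeline: strict consensus, Bremer supports, and
positional-instability (wildcard) analysis with reduced consensus.

A "position" of a taxon in a tree is the partition of the remaining leaves
into the components that surround its attachment node — for a binary tree,
the bipartition its pendant edge induces on the other leaves.  Taxa that
occupy many positions across the set of most-parsimonious trees (wildcards)
destroy consensus resolution; pruning them from every tree before taking
the strict consensus recovers the relationships the trees do agree on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .matrix import CharacterMatrix
from .search import TreeSet, suboptimal_pool
from .tree import Node, PhyloTree, connect

__all__ = ["ConsensusTree", "SupportReport", "InstabilityReport",
           "strict_consensus", "bremer_supports", "positional_instability",
           "prune_taxa"]


# ---------------------------------------------------------------------------
# strict consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusTree:
    """Strict (Nelsen) consensus: exactly the clades common to all inputs."""

    tree: PhyloTree
    n_input: int
    clades: frozenset[frozenset[str]]

    @property
    def n_resolved(self) -> int:
        return len(self.clades)

    def newick(self, outgroup: str | None = None) -> str:
        return self.tree.newick(outgroup=outgroup)


def _tree_from_clusters(labels: frozenset[str], ref: str,
                        clusters: Iterable[frozenset[str]]) -> PhyloTree:
    """Build the unrooted tree displaying exactly the given mutually
    compatible clusters (each a label set excluding ``ref``)."""
    clusters = sorted(set(clusters), key=len, reverse=True)
    root = Node()
    nodes: list[tuple[frozenset[str], Node]] = []
    leaf_map: dict[str, Node] = {}

    def smallest_containing(item: frozenset[str]) -> Node:
        for cl, nd in reversed(nodes):      # smallest first
            if item < cl:
                return nd
        return root

    for cl in clusters:
        node = Node()
        connect(smallest_containing(cl), node)
        nodes.append((cl, node))
    for lab in sorted(labels):
        leaf = Node(lab)
        leaf_map[lab] = leaf
        if lab == ref:
            connect(root, leaf)
        else:
            connect(smallest_containing(frozenset((lab,))), leaf)
    return PhyloTree(leaf_map)


def strict_consensus(treeset: TreeSet | Sequence[PhyloTree]) -> ConsensusTree:
    """Intersection of the bipartition sets of all input trees."""
    trees = list(treeset)
    if not trees:
        raise ValueError("consensus of an empty tree set")
    labels = trees[0].labels
    for t in trees[1:]:
        if t.labels != labels:
            raise ValueError("input trees have mismatched leaf sets")
    common = trees[0].bipartitions()
    for t in trees[1:]:
        common &= t.bipartitions()
    ref = min(labels)
    return ConsensusTree(tree=_tree_from_clusters(labels, ref, common),
                         n_input=len(trees), clades=frozenset(common))


# ---------------------------------------------------------------------------
# Bremer supports
# ---------------------------------------------------------------------------

@dataclass
class SupportReport:
    """Per-clade decay values: extra steps before the clade is lost.

    A value of ``None`` means the clade persisted in every tree up to
    ``best_length + k_max`` (reported as ">k_max")."""

    best_length: int
    k_max: int
    values: dict[frozenset[str], int | None]
    pool_complete: bool = True

    def as_rows(self) -> list[dict]:
        rows = []
        for clade, v in sorted(self.values.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            rows.append({"clade": ";".join(sorted(clade)),
                         "bremer": v if v is not None else f">{self.k_max}"})
        return rows


def _binary_trees(treeset: TreeSet) -> list[PhyloTree]:
    binary = treeset.provenance.get("binary_trees")
    if binary:
        return list(binary)
    if all(t.is_binary() for t in treeset.trees):
        return list(treeset.trees)
    raise ValueError(
        "tree set holds collapsed (polytomous) trees and no binary "
        "originals in provenance; pass a TreeSet produced by "
        "heuristic_search or exhaustive_search")


def bremer_supports(matrix: CharacterMatrix, treeset: TreeSet,
                    k_max: int = 6, cap: int = 10_000,
                    clades: Iterable[frozenset[str]] | None = None,
                    prune: Sequence[str] = ()) -> SupportReport:
    """Decay index for each consensus clade of an MPT set.

    All distinct trees within ``best + k_max`` are collected by
    suboptimal-retaining TBR from the MPTs; a clade's Bremer value is the
    smallest extra length at which some tree lacks it.  With ``prune``,
    clades are read on the pool trees after a-posteriori removal of the
    given taxa (supports for a reduced consensus).
    """
    if treeset.length is None:
        raise ValueError("tree set carries no length; not an MPT set")
    starts = _binary_trees(treeset)
    best, pool, complete = suboptimal_pool(matrix, starts, slack=k_max,
                                           cap=cap)
    if best < treeset.length:
        raise ValueError(
            f"tree set (length {treeset.length}) is not optimal: found "
            f"length {best}")
    if clades is None:
        if prune:
            pruned = prune_taxa(treeset, list(prune), mode="a_posteriori")
            clades = strict_consensus(pruned.trees).clades
        else:
            clades = strict_consensus(treeset.trees).clades
    clades = list(clades)
    values: dict[frozenset[str], int | None] = {c: None for c in clades}
    for tree, length in pool:
        k = length - best
        if prune:
            view = tree.copy()
            for lab in prune:
                view.prune_leaf(lab)
        else:
            view = tree
        splits = view.bipartitions()
        for c in clades:
            cur = values[c]
            if c not in splits and (cur is None or k < cur):
                values[c] = k
    return SupportReport(best_length=best, k_max=k_max, values=values,
                         pool_complete=complete)


# ---------------------------------------------------------------------------
# positional instability (PCR-style wildcard detection)
# ---------------------------------------------------------------------------

@dataclass
class InstabilityReport:
    """Positional variability of each taxon across an MPT set."""

    position_counts: dict[str, int]
    resolution_gains: dict[str, int]
    ranking: list[str] = field(default_factory=list)

    def most_unstable(self, n: int | None = None) -> list[str]:
        return self.ranking if n is None else self.ranking[:n]

    def as_rows(self) -> list[dict]:
        return [{"taxon": t, "positions": self.position_counts[t],
                 "resolution_gain": self.resolution_gains[t],
                 "pruned_rank": (self.ranking.index(t) + 1
                                 if t in self.ranking else None)}
                for t in sorted(self.position_counts)]


def taxon_positions(trees: Sequence[PhyloTree], label: str) -> int:
    """Number of distinct attachment positions of a taxon across trees."""
    seen = set()
    for t in trees:
        leaf = t.leaf_map[label]
        (v,) = leaf.nbrs
        parts = []
        for nbr in v.nbrs:
            if nbr is leaf:
                continue
            leaves = frozenset(
                n.label for n, _ in _iter_component(nbr, v) if n.is_leaf)
            parts.append(leaves)
        seen.add(frozenset(parts))
    return len(seen)


def _iter_component(start: Node, blocked: Node):
    stack = [(start, blocked)]
    while stack:
        node, parent = stack.pop()
        yield node, parent
        for nbr in node.nbrs:
            if nbr is not parent:
                stack.append((nbr, node))


def project_clades(clades: Iterable[frozenset[str]],
                   keep: frozenset[str]) -> set[frozenset[str]]:
    """Restrict clades to a leaf subset, canonicalized as bipartitions of
    the subset (complementary projections coincide)."""
    ref = min(keep)
    out = set()
    for b in clades:
        side = frozenset(b & keep)
        if ref in side:
            side = frozenset(keep - side)
        if 2 <= len(side) <= len(keep) - 2:
            out.add(side)
    return out


def _stats_for(trees: list[PhyloTree]) -> tuple[dict, dict]:
    labels = trees[0].labels
    full_cons = strict_consensus(trees)
    counts, gains = {}, {}
    for lab in sorted(labels):
        counts[lab] = taxon_positions(trees, lab)
        keep = labels - {lab}
        pruned = TreeSet.dedup(t.restricted(keep) for t in trees)
        reduced = strict_consensus(pruned)
        gains[lab] = reduced.n_resolved - len(
            project_clades(full_cons.clades, keep))
    return counts, gains


def positional_instability(treeset: TreeSet | Sequence[PhyloTree]
                           ) -> InstabilityReport:
    """Rank wildcard taxa: per-taxon attachment-position counts and the
    strict-consensus resolution gained by pruning each.  Pruning proceeds
    greedily (best gain first, ties by position count, then label) and
    re-evaluates the remaining taxa after each removal."""
    trees = list(treeset)
    if len(trees) < 2:
        labels = sorted(trees[0].labels) if trees else []
        return InstabilityReport({t: 1 for t in labels},
                                 {t: 0 for t in labels}, [])
    counts, gains = _stats_for(trees)
    ranking: list[str] = []
    cur = trees
    cur_counts, cur_gains = counts, gains
    while True:
        candidates = sorted(
            cur_counts,
            key=lambda t: (-cur_gains[t], -cur_counts[t], t))
        top = candidates[0]
        if cur_gains[top] <= 0 or len(cur[0].labels) <= 4:
            break
        ranking.append(top)
        keep = cur[0].labels - {top}
        cur = TreeSet.dedup(t.restricted(keep) for t in cur)
        if len(cur) < 2:
            break
        cur_counts, cur_gains = _stats_for(cur)
    return InstabilityReport(counts, gains, ranking)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_taxa(target: CharacterMatrix | TreeSet, taxa: Sequence[str],
               mode: str):
    """Remove taxa either from the matrix before a re-run (``a_priori``)
    or from every tree of an MPT set (``a_posteriori``), deduplicating the
    resulting topologies."""
    if mode not in ("a_priori", "a_posteriori"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(target, CharacterMatrix):
        if mode != "a_priori":
            raise ValueError("a matrix can only be pruned a priori "
                             "(the search must be re-run)")
        return target.drop_taxa(list(taxa))
    if isinstance(target, TreeSet):
        if mode != "a_posteriori":
            raise ValueError("a tree set can only be pruned a posteriori")
        missing = set(taxa) - (target.trees[0].labels if target.trees else set())
        if missing:
            raise KeyError(f"labels not in trees: {sorted(missing)}")
        keep = target.trees[0].labels - set(taxa)
        pruned = TreeSet.dedup(t.restricted(keep) for t in target.trees)
        prov = dict(target.provenance)
        prov["pruned_a_posteriori"] = sorted(taxa)
        prov.pop("binary_trees", None)
        return TreeSet(trees=pruned, length=target.length, provenance=prov)
    raise TypeError(f"cannot prune {type(target).__name__}")
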