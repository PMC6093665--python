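"""Synthetic morphological matrices with known generating trees.

Characters evolve by placing a fixed number of state-change events on
random branches of a random tree — a direct homoplasy dial for parsimony:
the generating tree can never require more steps than the number of events,
and with one event per character it is guaranteed to be an optimum.  This
event-count scheme is deliberately simpler than a continuous-time Mk
process; it trades rate realism for exact, testable control of the
quantity parsimony actually responds to.

Defaults mirror the shape of a typical aetosaur-scale morphological
matrix: a few dozen taxa, ~80 characters with 2-4 states, a small additive
(ordered) fraction, and a substantial share of missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, CharacterMatrix, StateSet
from .tree import Node, PhyloTree, connect

__all__ = ["SimConfig", "SimTruth", "simulate_tree", "simulate_matrix",
           "simulate_dataset"]


@dataclass
class SimConfig:
    """Generator settings; fractions are per-cell probabilities."""

    n_taxa: int = 28
    n_characters: int = 83
    min_states: int = 2
    max_states: int = 4
    ordered_prob: float = 7 / 83
    events_per_char: int = 2
    missing_fraction: float = 0.25
    polymorphic_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3 or self.n_characters < 1:
            raise ValueError("need >=3 taxa and >=1 character")
        if not 2 <= self.min_states <= self.max_states <= 10:
            raise ValueError("state counts must satisfy 2 <= min <= max <= 10")
        for frac in (self.missing_fraction, self.polymorphic_fraction,
                     self.ordered_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.events_per_char < 0:
            raise ValueError("events_per_char must be >= 0")


@dataclass
class SimTruth:
    """Ground truth serialized next to a simulated matrix."""

    tree: PhyloTree
    events_per_char: list[int]
    ordered: list[bool]
    seed: int | None = None

    @property
    def total_events(self) -> int:
        return int(sum(self.events_per_char))

    def as_dict(self) -> dict:
        return {"tree_newick": self.tree.newick(),
                "events_per_char": list(self.events_per_char),
                "ordered": list(self.ordered),
                "total_events": self.total_events,
                "seed": self.seed}


def default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def simulate_tree(n_taxa: int, rng: np.random.Generator,
                  labels: list[str] | None = None) -> PhyloTree:
    """Uniform random unrooted binary topology via random stepwise
    addition (every attachment branch equally likely)."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = labels if labels is not None else default_labels(n_taxa)
    if len(labels) != n_taxa:
        raise ValueError("label count must equal n_taxa")
    tree = PhyloTree.star(labels[:3])
    for lab in labels[3:]:
        edges = tree.edges()
        u, v = edges[rng.integers(len(edges))]
        mid = Node()
        u.nbrs.remove(v)
        v.nbrs.remove(u)
        connect(u, mid)
        connect(mid, v)
        leaf = Node(lab)
        connect(mid, leaf)
        tree.leaf_map[lab] = leaf
    return tree


def _mutate(state: int, n_states: int, ordered: bool,
            rng: np.random.Generator) -> int:
    if ordered:
        if state == 0:
            return 1
        if state == n_states - 1:
            return state - 1
        return state + (1 if rng.random() < 0.5 else -1)
    other = rng.integers(n_states - 1)
    return int(other if other < state else other + 1)


def simulate_matrix(tree: PhyloTree, config: SimConfig,
                    rng: np.random.Generator
                    ) -> tuple[CharacterMatrix, SimTruth]:
    """Evolve characters on a tree by event placement, then apply missing
    and polymorphic masks.  Returns the matrix and its ground truth."""
    post = tree.postorder()
    edges = [(p, n) for n, p in post if p is not None]
    labels = sorted(tree.labels)
    cells: dict[str, list[StateSet]] = {lab: [] for lab in labels}
    ordered_flags, event_counts = [], []
    for _ in range(config.n_characters):
        n_states = int(rng.integers(config.min_states, config.max_states + 1))
        ordered = bool(rng.random() < config.ordered_prob)
        n_events = config.events_per_char
        hits = np.zeros(len(edges), dtype=int)
        for _ in range(n_events):
            hits[rng.integers(len(edges))] += 1
        state: dict[Node, int] = {}
        root = post[-1][0]
        state[root] = int(rng.integers(n_states))
        # preorder propagation: parents are assigned before their children
        for (parent, node), k in zip(edges[::-1], hits[::-1]):
            s = state[parent]
            for _ in range(int(k)):
                s = _mutate(s, n_states, ordered, rng)
            state[node] = s
        ordered_flags.append(ordered)
        event_counts.append(n_events)
        for lab in labels:
            leaf_state = state[tree.leaf_map[lab]]
            u = rng.random()
            if u < config.missing_fraction:
                cells[lab].append(MISSING)
            elif u < config.missing_fraction + config.polymorphic_fraction \
                    and n_states >= 2:
                extra = _mutate(leaf_state, n_states, ordered, rng)
                cells[lab].append(StateSet.of(leaf_state, extra))
            else:
                cells[lab].append(StateSet.of(leaf_state))
    matrix = CharacterMatrix(
        taxa=labels, cells=[cells[lab] for lab in labels],
        ordered=ordered_flags, title="simulated")
    truth = SimTruth(tree=tree, events_per_char=event_counts,
                     ordered=ordered_flags, seed=config.seed)
    return matrix, truth


def simulate_dataset(config: SimConfig
                     ) -> tuple[CharacterMatrix, SimTruth]:
    """Tree + matrix from a single seed; the one-call entry point."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_taxa, rng)
    matrix, truth = simulate_matrix(tree, config, rng)
    return matrix, truth
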