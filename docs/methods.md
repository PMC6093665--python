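# Methods

## Model and scoring

Characters are discrete morphological columns over the integer alphabet
0–9.  Under equally weighted parsimony the score of a topology is the sum
over characters of the minimum number of state changes, where a change
from state *i* to *j* costs 1 for unordered (non-additive) characters and
|i − j| for ordered (additive) ones.  Both cost regimes are computed by a
single vectorized minimum-cost dynamic program over the state line (a
Sankoff-style pass, `numpy` arrays of shape characters × states per tree
node).  On binary trees this reproduces classical Fitch and Farris
optimization exactly; unlike the set-based passes it remains exact on
multifurcations, which collapsed trees require.  The unit-cost child
transform is `g(s) = min(c(s), min_t c(t) + 1)`; the additive transform is
a two-sweep distance transform along the state axis.  Missing cells
(`?` and `-` alike — discrete morphology has no separate gap semantics)
are encoded as zero cost for every state; polymorphic cells as zero cost
for each listed state, i.e. ambiguity rather than fixed polymorphism, and
for ordered characters this makes the cell behave as its enclosing
interval.  Tests verify the engine against an independent pure-Python
Sankoff recursion on random trees and columns, including missing and
polymorphic cells.

Per-edge minimum lengths — the number of changes an internal edge carries
in the most change-free optimal reconstruction — are obtained from the
same pass run in both directions (down/up arrays), combining the two
directed cost vectors with the full substitution-cost matrix and reading
off the cheapest edge cost among globally optimal state pairs.

## Heuristic search

The search replicates the "traditional search" protocol: each replicate
draws a random taxon addition sequence, builds a Wagner tree by stepwise
insertion at the length-minimizing branch (ties broken uniformly by the
run's RNG), then applies tree-bisection-reconnection (TBR) swapping.  A
strictly shorter neighbor restarts swapping immediately; equally short
new topologies are kept up to the per-replicate hold (default 10).  Best
trees from all replicates (default 100) are pooled and a final TBR round
runs over the pool with the hold lifted to the global tree-buffer cap
(default 10,000): per-replicate holds alone cannot recover the full set
of equally parsimonious trees, which is what the reported MPT counts
refer to.  Reaching the cap flags the result incomplete.

TBR neighborhoods are evaluated without materializing neighbor trees:
cutting an edge leaves two fragments; edge-rooted cost arrays for every
attachment point of both fragments are computed in two passes, after
which every reconnection is scored by one broadcast array operation.
Trees are instantiated only when accepted.  The enumerator is tested
against an independent characterization of TBR distance 1 (an
agreement-split argument) on six-leaf trees.

Tree identity throughout is the set of non-trivial bipartitions after
collapsing.  Zero-length branches are collapsed by rule 1 — delete
internal branches whose minimum length over all optimal reconstructions
is zero — applied iteratively: one zero-minimum edge is contracted at a
time (deterministically, smallest bipartition first) and the minima
recomputed.  Simultaneous contraction would be wrong: two edges can each
admit a change-free optimal reconstruction without admitting one jointly,
so collapsing them together can lengthen the tree, whereas single
contractions provably preserve length and iteration to a fixed point
makes the operation idempotent.

An exhaustive enumerator (stepwise addition over all branches,
(2n−5)!! topologies) provides exact optima up to 9 taxa and anchors the
oracle tests: on simulated ≤7-taxon matrices the heuristic is required to
match the exhaustive best length and, swapped to saturation, the full
optimum set.

## Consensus, Bremer support, wildcards

The strict (Nelsen) consensus is the bipartition-set intersection of the
input trees, rebuilt as a tree from the common clusters; containment of
the consensus clades in every input tree is asserted per run, and the
construction is cross-checked against an independent library
implementation in the tests.

Bremer (decay) values are computed from suboptimal pools: a
TBR sweep seeded from the binary MPTs retains every distinct tree within
`best + k_max` (default `k_max` 6; the buffer cap applies and is
reported).  A clade's value is the smallest extra length at which some
pool tree lacks it; clades surviving the whole pool are reported as
`>k_max`.  This is equivalent to growing k-pools incrementally, and on
≤7-taxon instances the values are tested to equal the exhaustive
definition: (shortest topology lacking the clade) − (best length).
Converse-constraint searches would be faster on large matrices but are
not needed at the scales this package targets.

A taxon's *position* in a tree is the partition of the remaining leaves
into the components around its attachment node (for binary trees, the
bipartition its pendant edge induces).  The instability report counts
distinct positions across the MPT set and, for each taxon, the
resolution gained by pruning it: resolved clades of the strict consensus
of the pruned trees minus resolved clades of the full consensus projected
onto the remaining leaves (projected splits are canonicalized as
bipartitions, since two clades may project to complementary sides of the
same split).  Ranking is greedy — highest gain first, ties by position
count then label — re-evaluating after each pruning, and stops when no
taxon yields a positive gain.  This is the reduced-consensus variant of
positional-congruence screening; the full character-congruence iterative
refinement of that methodology is intentionally out of scope.

A-priori pruning removes matrix rows (the search must be re-run);
a-posteriori pruning removes leaves from every tree of a set, suppresses
the resulting degree-2 nodes and deduplicates, which can only reduce the
number of distinct topologies.

## Two-stage pipeline

`run_paper_pipeline` wires the stages: parse (optionally merge OTUs and
apply audited cell re-scorings) → search → strict consensus + instability
ranking → exclude the ranked wildcards a priori → re-search → consensus →
prune any remaining unstable taxon a posteriori → reduced consensus with
Bremer supports.  Supports are evaluated for the reduced-consensus clades
by applying the same pruning to each pool tree, matching how supports are
drawn on a reduced consensus.  All randomness flows from one seed
(stage 2 uses seed+1); reports are byte-identical across reruns, every
reported number is re-derivable from the emitted Newick trees plus the
matrix (asserted in tests), and the matrix digest and configuration are
embedded in the report.

The shipped `configs/replication.yaml` encodes the published protocol
(100 replicates, hold 10, rule-1 collapsing, *Postosuchus kirkpatricki*
as display-only outgroup — parsimony length is root-invariant, so rooting
never affects scoring).  The additive set of the target matrix is
declared in that matrix's original source publication; with
`replication: true` the pipeline refuses to run while every character is
unordered rather than silently producing a non-comparable length.

## Synthetic data

The generator draws a uniform random unrooted binary topology (random
stepwise addition; uniformity is chi-square-checked in the tests) and
evolves each character by placing a configured number of change events on
uniformly chosen branches — unordered characters jump to a uniformly
chosen other state, ordered characters step ±1 (reflecting at the ends of
the state line).  Missing and polymorphic masks are applied per cell
afterwards.  Event counts give direct control of homoplasy: the
generating tree never requires more steps than the number of events, and
with one event per character it is exactly optimal, which the recovery
tests exploit.  Defaults (28 taxa, 83 characters, 2–4 states,
ordered fraction ≈ 7/83, 2 events per character, 25% missing cells, 1%
polymorphic) mirror the shape of an aetosaur-scale morphological matrix.
What the generator does not model: correlated characters, ascertainment
bias toward variable characters, clock-like rate structure, and
non-random missingness (real fossils lose anatomical regions, not random
cells) — so passing recovery tests demonstrate algorithmic correctness,
not expected performance on real specimens.

## Numerical and size choices

State space is capped at the observed alphabet (≥2 states); infeasible
states carry a large finite sentinel cost (2^20) in 64-bit integer
arrays, so no overflow or floating-point comparisons arise.  Exhaustive
enumeration refuses above 9 taxa (135,135 topologies).  The test-suite
and acceptance-script problem sizes — ≤8 taxa for oracle equivalence, 10
taxa for the pipeline contract, 16 taxa × 83 characters for the
study-shaped demonstration with 5 replicates — were chosen so the exact
oracles stay enumerable and a complete run remains a desk-scale
computation; the search scales to the full 28-taxon protocol.
Determinism: a single integer seed drives addition orders and all
tie-breaks; candidate enumeration order is structural, and Newick output
is canonical (children sorted by smallest descendant label), so equal
topologies always serialize identically.

## Known limitations

- No implied weighting, ratchet, sectorial search or tree fusing; the
  target protocol uses traditional search only.
- No continuous, Dollo or step-matrix characters; weights are all 1.
- Bremer pools (and hence values) are exact only as far as TBR from the
  MPTs explores; the buffer cap can truncate pools on large matrices
  (flagged in the report).
- Bootstrap/jackknife resampling supports and majority-rule consensus are
  deliberately absent.
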