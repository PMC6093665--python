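# maxpars

Equally weighted maximum parsimony for discrete morphological character
matrices, built for systematists who analyze TNT/NEXUS matrices of the
kind used in vertebrate paleontology (the shipped replication config
targets an aetosaur matrix of 83 characters × 28 operational taxonomic
units, including the referred skull specimen UFSM 11505 of
*Aetosauroides scagliai*).

The package covers the whole analysis loop:

- **Matrix I/O and editing** — TNT `xread` and NEXUS dialects, `?`/`-`
  missing cells, `[01]` polymorphic cells, additive-character declarations
  (`ccode` / `TYPESET`), OTU merging and audited cell re-scorings.
- **Scoring** — per-character minimum-change counts with unordered (Fitch)
  and ordered/additive (Farris) costs, exact on polytomies, plus per-edge
  minimum lengths for zero-length-branch collapsing.
- **Search** — random-addition Wagner starting trees refined by TBR branch
  swapping (the "traditional search": *R* replicates holding *h* trees
  each, a final pooled TBR round, rule-1 collapsing), and a complete
  enumeration oracle for ≤9 taxa.
- **Post-search** — strict (Nelsen) consensus, Bremer (decay) supports
  from suboptimal tree pools, positional-instability ranking of wildcard
  taxa, and a-priori / a-posteriori pruning with reduced consensus.
- **Simulation** — matrices evolved on known trees with a direct homoplasy
  dial (events per character), for validation end to end.

## The quantities computed

For a tree *T* and characters *c*, the tree length is
`L(T) = Σ_c min #changes(c, T)`, where a change between states *i* and *j*
costs 1 for unordered characters and `|i − j|` for ordered (additive)
ones; missing cells are maximally ambiguous and never add cost.  A most
parsimonious tree (MPT) minimizes `L`.  Bremer support of a clade is the
extra length needed before some tree lacks the clade; a wildcard taxon is
one whose attachment position varies across MPTs, and pruning it from the
trees (not the matrix) yields the reduced strict consensus.

## Worked example

```python
import maxpars as mp

# simulate a 10-taxon, 30-character matrix with moderate homoplasy
cfg = mp.SimConfig(n_taxa=10, n_characters=30, events_per_char=3,
                   missing_fraction=0.3, seed=11)
matrix, truth = mp.simulate_dataset(cfg)

ts = mp.heuristic_search(matrix, mp.SearchConfig(n_replicates=5, seed=2))
print(ts.length, len(ts))          # -> 53 15
cons = mp.strict_consensus(ts)
print(cons.n_resolved)             # -> 1
pcr = mp.positional_instability(ts)
print(pcr.most_unstable(1))        # -> ['t09']
```

The search finds a best length of 53 steps attained by 15 distinct
rule-1-collapsed trees; their strict consensus keeps only a single
resolved clade because taxon `t09` (a wildcard under this seed) floats
between positions — exactly the situation the instability ranking is
designed to flag.  Excluding it and re-running (what
`mp.run_paper_pipeline` automates) gives a single MPT of 46 steps.

The same analyses are scriptable from the shell:

```bash
maxpars simulate --taxa 10 --chars 30 --events 3 --seed 11 --out-prefix sim
maxpars search run --matrix sim.tnt --reps 5 --seed 2 --out mpts.nwk
maxpars consensus --trees mpts.nwk
maxpars pipeline run --matrix sim.tnt --seed 2 --out report/
```

`configs/replication.yaml` encodes the published aetosaur protocol
(100 replicates, hold 10, TBR, rule-1 collapsing, *Postosuchus
kirkpatricki* as display outgroup) for use with the deposited
83 × 28 supplementary matrix placed at `data/aetosaur_s1.tnt`.

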