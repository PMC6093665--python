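# Replication protocol for the published aetosaur analysis:
# traditional search, 100 random-addition Wagner + TBR replicates holding
# 10 trees each, rule-1 collapsing, Postosuchus kirkpatricki as outgroup
# (display rooting only; Revueltosaurus callenderi is the second outgroup).
#
# Run against the deposited supplementary character/taxon matrix
# (83 characters x 28 taxa), expected at data/aetosaur_s1.tnt:
#
#   maxpars pipeline run --matrix data/aetosaur_s1.tnt \
#       --config configs/replication.yaml --seed 1 --out report/
#
# The seven additive (ordered) characters are declared in the matrix's
# original publication, not in the analysis paper; list their 1-based
# indices under ordered_characters (or embed a ccode block in the matrix
# file).  With replication: true the pipeline refuses to run while every
# character is unordered, so a forgotten declaration cannot silently
# produce a non-comparable tree length.
n_replicates: 100
hold_per_replicate: 10
max_trees: 10000
outgroup: Postosuchus_kirkpatricki
replication: true
ordered_characters: []   # fill from the source matrix publication
k_max: 6
# The deposited matrix already contains the published OTU merge
# (SMSN 19003 into Paratypothorax andressorum) and cell re-scorings; when
# starting instead from the earlier source matrix, apply
# configs/rescoring_edits.yaml with `maxpars matrix edit` and merge with
# `maxpars matrix merge` first.
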