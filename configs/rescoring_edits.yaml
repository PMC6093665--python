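# Published cell re-scorings (1-based character numbers).
#
# Five previously unknown cranial characters scored for the referred
# skull specimen UFSM 11505:
- {taxon: UFSM_11505, char: 1, new: 1}
- {taxon: UFSM_11505, char: 12, new: 0}
- {taxon: UFSM_11505, char: 13, new: 0}
- {taxon: UFSM_11505, char: 31, new: 1}
- {taxon: UFSM_11505, char: 35, new: 0}
# Four modified scorings for the Aetosauroides scagliai holotype row
# (old -> new; char 35 becomes unknown):
- {taxon: Aetosauroides_scagliai, char: 5, old: 0, new: 1}
- {taxon: Aetosauroides_scagliai, char: 19, old: 1, new: 0}
- {taxon: Aetosauroides_scagliai, char: 30, old: 0, new: 1}
- {taxon: Aetosauroides_scagliai, char: 35, old: 0, new: null}
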