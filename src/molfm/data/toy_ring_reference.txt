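# Toy ring-system reference bundled with molfm: one molecule SMILES per line;
# ring-system keys are extracted through the same canonicalization used at
# evaluation time. Stand-in for a large-scale reference catalog (e.g. ring
# systems observed in ChEMBL), which users supply as their own file.
c1ccccc1
c1ccncc1
c1cncnc1
c1cc[nH]c1
c1ccoc1
c1ccsc1
c1cnc[nH]1
c1ocnc1
c1ccc2ccccc2c1
C1CC1
C1CCC1
C1CCCC1
C1CCCCC1
C1CO1
C1CN1
C1COC1
C1CCOC1
C1CCOCC1
C1CCNC1
C1CCNCC1
C1CNCCN1
C1COCCN1
C1=CCCC1
C1=CCCCC1
O=C1CCC1
O=C1CCCC1
O=C1CCCCC1
O=C1CCNC1
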