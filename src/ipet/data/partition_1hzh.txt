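# Default IgG1 domain partition for an intact antibody crystal structure
# with heavy chains H/K and light chains L/M (e.g. PDB entry 1HZH).
# Residue boundaries are approximate EU-type numbering and editable:
# CH2 ~ 238-340 and CH3 ~ 341-443 of each heavy chain.
# Format: LABEL CHAIN RANGE  (RANGE is start-end inclusive, or * for all)
Fab1 H 1-220
Fab1 L *
Fab2 K 1-220
Fab2 M *
hinge H 221-237
hinge K 221-237
HalfFcA_CH2 H 238-340
HalfFcA_CH3 H 341-443
HalfFcB_CH2 K 238-340
HalfFcB_CH3 K 341-443
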