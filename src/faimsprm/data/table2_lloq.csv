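gene,peptide,z,lloq_faims_amol_per_ug,lloq_nofaims_amol_per_ug,best_fragment
EGFR,IPLENLQIIR,2,46,137,y8
EGFR,YLVIQGDER,2,412,412,y7
ERBB2,ELVSEFSR,2,46,137,y5
ERBB2,FVVIQNEDLGPASPLDSTFYR,3,137,412,y8
ERBB2,FVVIQNEDLGPASPLDSTFYR,2,137,137,y12
ERBB2,SGGGDLTLGLEPSEEEAPR,2,46,137,y11
ESR1,LLFAPNLLLDR,2,15,15,y7; y8
KRAS,LVVVGACGVGK,2,46,137,y9
KRAS,LVVVGAGGVGK,2,46,46,y9
MET,DLIGFGLQVAK,2,137,412,y9
MET,TEFTTALQR,2,137,412,y7
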