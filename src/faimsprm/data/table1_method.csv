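gene,peptide,z,mz_light,cv_volts,ce,rt_min
EGFR,IPLENLQIIR,2,604.87,-58,24,27.4
EGFR,YLVIQGDER,2,546.79,-48,23,13.1
ERBB2,ELVSEFSR,2,483.75,-58,22,14.3
ERBB2,FVVIQNEDLGPASPLDSTFYR,2,1184.59,-28,23,32.8
ERBB2,FVVIQNEDLGPASPLDSTFYR,3,790.07,-58,19,32.8
ERBB2,SGGGDLTLGLEPSEEEAPR,2,957.46,-38,22,21.5
ESR1,LLFAPNLLLDR,2,642.89,-44,23,37.1
KRAS,LVVVGACGVGK,2,529.81,-48,21,12.8
KRAS,LVVVGAGGVGK,2,478.30,-52,18,11.5
MET,DLIGFGLQVAK,2,580.84,-38,19,30.6
MET,TEFTTALQR,2,533.78,-58,22,14.0
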