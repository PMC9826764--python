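ATM
FGFR1
FBXW7
ESR1
CCND1
HIF1A
CEBPB
NAMPT
KYNU
IRF1
SOCS1
ICAM1
ETS1
IL7R
MMP1
HNF4A
CCL2
CASP1
STAT1
SOCS3
HSP90B1
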