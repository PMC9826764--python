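ARHGEF10
QKI
ETS1
IFITM2
GPCPD1
ZEB2
OSBPL3
SOCS3
CCL2
CADM1
DDAH2
CEBPB
ACSL1
NAMPT
TFPI2
HIF1A
ADAMTS2
SCD
TRAM2
PFKFB3
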