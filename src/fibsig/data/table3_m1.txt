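ICAM1
ADAMTS2
CASP1
SETX
IFITM2
PGM3
TNFRSF1B
CDKN2B
ZKSCAN1
ZEB2
MRPS25
PHF21A
TUBB6
HSP90B1
LTN1
SPRYD7
ATP9A
PHLDA1
CASP4
STX11
MBNL3
RPS6KA2
PAPSS2
RAMP3
NAMPT
VCP
ESR1
ANXA3
ADAM9
MMP1
KYNU
OCRL
S100A11
TGM2
ATP6V1C1
PHTF1
BAG2
HSPA13
RHOQ
TNC
ACSL1
RECQL
SSR1
TRIB1
SLC7A11
NUCB2
BCAT1
RABGAP1
DRAM1
IL1RAP
IRF1
TRAM2
BHLHE40
SERPING1
MMP14
CALD1
HNF4A
STAT1
CEBPB
CXCL5
OSBPL3
ARMCX3
CCND1
DYRK2
SOCS3
PTPN21
PSME1
TPM4
RRM2
HLA-DQB1
RYBP
SORL1
MYCBP2
GM2A
AQP9
LETM1
IGFBP7
ATM
SOCS1
FLT3
PRRC2C
CFB
EIF4EBP2
CLEC7A
COL4A1
DLG1
NRP2
TFPI2
NUP210
CADM1
IL7R
FBXW7
HIF1A
PRKD3
CD3E
KIAA0930
ATRX
DEF8
PFKFB3
CCL2
THEMIS2
FGFR1
SKIL
OLFM1
ETS1
GPCPD1
NEDD4L
TRIM22
THRA
QKI
CNBP
MTDH
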