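ICAM1
VCP
SLC16A5
TRAM2
HSP90B1
OGFR
AP3D1
CDKN2B
ZKSCAN1
TGM2
SSR1
RAB17
RPS6KA2
HNRNPU
PDS5A
SPRYD7
ATP9A
RECQL
IRF1
ABCA5
TPK1
SMARCA2
CCND1
SASH1
NAMPT
IL1RAP
CEBPB
CXCL5
AVIL
SLC9A6
ROCK2
RAMP3
S100A11
STAT1
PSME1
TPM4
HADHA
CDC6
UBXN4
OCRL
SUPT4H1
PTPN21
HDLBP
LETM1
MMP1
MELTF
TAOK3
SLC4A7
ASPH
PPM1A
AQP9
CLEC7A
PDLIM2
TCF12
STRN
TNC
ACSL1
GM2A
PLCB1
FBXW7
TMEM38B
HNRNPH3
GATAD1
SS18L1
DRAM1
TMEM41B
EIF4EBP2
CCL2
HSPA13
CALM3
MUT
RABGAP1
VNN1
ATP2C1
IL7R
TRIM22
NUCB2
RAP1A
RMND5A
CCNT2
C1QA
SYNGR2
PYHIN1
SCD
SERPING1
ENDOD1
DST
EIF4G3
HNF4A
CFB
TRABD
TMEM184B
ARMCX3
QKI
KIAA1109
DCAF4
SOCS3
CADM1
PATJ
IFITM2
HLA-DQB1
TNFRSF1B
NDUFA5
CALD1
XPO1
SNX13
RANBP9
TUBB6
NOL7
LRPPRC
RYBP
DYRK2
MYCBP2
ARF6
PFKFB3
MBNL3
SMC3
LTN1
SOCS1
NDUFAF3
PRRC2C
DEF8
MLLT10
ADAM9
PHACTR2
PAPSS2
ARHGEF10
SORL1
NUP210
GPCPD1
BMPR1A
BAG2
PGLYRP1
MEST
DLD
SPAG9
ATRX
DDAH2
NEDD4L
HEXIM1
KAT6B
RRAS2
CHMP2B
CDC5L
LIMK1
CASP1
TUSC2
SLC7A11
CD58
ZNF292
NRP2
SERHL2
NDUFA6
FBXL20
SYF2
BHLHE40
ATM
ZNF43
PPP6C
FLT3
ETS1
MRPS25
SETX
OSBPL3
PHF3
KYNU
CREBL2
TFPI2
ADAMTS2
CLDN1
PHF21A
RRM2
DLG1
RHOQ
API5
PLA2R1
SPON1
MIEN1
STX11
IGFBP7
FOXN3
SERBP1
GMFB
KIAA0930
PEX1
CASP4
CBFA2T2
COL4A1
REL
OAZ1
SEMA3F
BRD3
ZEB2
DAAM1
GIGYF2
RARRES3
ITGA6
SCAMP3
CD3E
TNPO2
RNF14
ARHGAP1
ANXA3
HIF1A
PRKD3
SBF1
SKIL
MECOM
APPBP2
ESR1
PHTF1
ARMC8
ARHGAP5
BCAT1
RNF6
KBTBD11
PAFAH1B1
COBLL1
EDN2
THEMIS2
MGAT5
MMP14
GSR
CDC14B
PAX8
ATP6V1C1
TAF4
THRA
FGFR1
NDUFB8
FEZ2
UBE4A
PHLDA1
ZNF81
TRIB1
PGM3
NIPAL3
NFYC
CNBP
OLFM1
MTDH
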