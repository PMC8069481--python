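ATM
ATR
ATRIP
ATRX
BAP1
BARD1
BLM
BRCA1
BRCA2
BRIP1
CHEK1
CHEK2
DNA2
EME1
EME2
ERCC1
ERCC4
EXO1
FANCA
FANCB
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCI
FANCL
FANCM
GEN1
HELQ
HROB
KAT5
MCM8
MCM9
MDC1
MRE11
MUS81
NBN
PALB2
PAXIP1
POLD1
POLQ
RAD50
RAD51
RAD51AP1
RAD51B
RAD51C
RAD51D
RAD52
RAD54B
RAD54L
RBBP8
RECQL
RECQL4
RECQL5
RMI1
RMI2
RNF168
RNF8
RPA1
RPA2
RPA3
RPA4
SEM1
SLX1A
SLX4
SPIDR
SWI5
SWSAP1
TOP3A
TOP3B
TOPBP1
TP53BP1
UIMC1
USP11
WRN
XRCC2
XRCC3
ABRAXAS1
BABAM1
BABAM2
BOD1L1
BRCC3
DCLRE1A
DCLRE1B
UBE2T
FAAP20
FAAP24
FAAP100
ZRANB3
SMARCAL1
HLTF
PARPBP
RTEL1
PIF1
FBXO18
H2AFX
INO80
NSMCE2
SMC5
SMC6
ZSWIM7
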