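KRT1
BCL2
TYSND1
DHRS4
EPHX2
IFNG
CCL5
MYC
SRC
PRDX4
GSS
HACL1
DNAJA3
GSTP1
PRDX2
PTGS2
HSPD1
FMO5
DNAJC9
CCT4
IL12RB1
HSPA9
CROT
CCT3
JUN
SLC27A2
GSR
JAK2
DNAJC5
DNAJC4
RHOU
GCLM
MSRA
SOCS3
PECR
CYP1B1
ARG1
CAT
SOD1
SOD2
SOD3
GPX1
GPX2
GPX3
GPX4
GPX5
GPX6
GPX7
GPX8
TXN
TXN2
TXNRD1
TXNRD2
TXNRD3
PRDX1
PRDX3
PRDX5
PRDX6
NQO1
NFE2L2
KEAP1
HMOX1
HMOX2
GCLC
GSTA1
GSTA2
GSTA4
GSTM1
GSTM2
GSTM3
GSTO1
GSTO2
GSTT1
GSTT2
MGST1
MGST2
MGST3
NOX1
NOX3
NOX4
NOX5
CYBA
CYBB
NCF1
NCF2
NCF4
DUOX1
DUOX2
XDH
MAOA
MAOB
ALOX5
ALOX12
ALOX15
NOS1
NOS2
NOS3
SESN1
SESN2
SESN3
OXR1
OXSR1
ATOX1
CCS
GLRX
GLRX2
GLRX3
GLRX5
SRXN1
MSRB1
MSRB2
MSRB3
FOXO1
FOXO3
FOXO4
MPO
EPX
LPO
TPO
PON1
PON2
PON3
AKR1B1
AKR1C1
ALDH3A1
CP
SELENOS
SELENOP
UCP2
UCP3
PARK7
SIRT1
SIRT3
APOE
G6PD
IDH1
NNT
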