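# Synthetic stand-in for the GO:0009986 'cell surface' membership list (519 symbols).
# Real surface/ADC-target symbols padded with generated placeholders; for pipeline testing only.
SLC7A11
MSLN
ENPP3
CD70
ERBB2
SLC44A4
FOLH1
SLC39A6
STEAP1
EGFR
FOLR1
CA6
KIT
ITGA5
EPHA2
F3
FGFR2
CA9
DLL3
EFNA4
LYPD3
TPBG
CDH3
PVRL4
TACSTD2
CDH17
SDC1
SEZ6L2
SLC34A2
MET
AXL
CD19
CD22
CD33
CD274
PDCD1LG2
EPCAM
GPNMB
NECTIN4
ROR1
ROR2
TNFRSF8
CEACAM5
MUC1
MUC16
PSCA
CLDN6
CLDN18
FGFR3
IGF1R
ITGB1
ITGB3
ITGAV
NCAM1
ALCAM
BSG
CD44
CD47
CD24
THY1
PROM1
L1CAM
LRP6
NOTCH1
NOTCH3
JAG1
DLL1
PTK7
TFRC
SLC3A2
ABCB1
ABCG2
ATP1A1
CDH1
CDH2
CDH5
ICAM1
VCAM1
SELE
SELP
SELL
ITGA2
ITGA3
ITGA6
ITGB4
ITGB5
CD4
CD8A
CD3E
CD3D
CD3G
CD2
CD5
CD6
CD7
CD9
CD14
CD36
CD38
CD40
CD48
CD53
CD58
CD63
CD69
CD80
CD86
CD96
CD151
CD163
CD200
CD226
CD276
CD300A
FAS
FASLG
TNFRSF1A
TNFRSF1B
TNFRSF10A
TNFRSF10B
TNFRSF14
TNFSF10
IL2RA
IL2RB
IL2RG
IL3RA
IL4R
IL6R
IL7R
IL10RA
IL13RA2
CSF1R
CSF2RA
CSF3R
KDR
FLT1
FLT3
FLT4
PDGFRA
PDGFRB
NGFR
NTRK1
NTRK2
EPHB2
EPHB4
EPHA4
EFNB2
PLAUR
PLXNB1
NRP1
NRP2
ROBO1
UNC5B
DCC
SLIT2
SEMA4D
LRP1
LDLR
SCARB1
MSR1
MRC1
MARCO
STAB1
SIRPA
SIGLEC1
SIGLEC7
KLRD1
KLRK1
NCR1
FCGR1A
FCGR2A
FCGR3A
FCER1G
PIGR
TLR2
TLR4
HAVCR2
LAG3
CTLA4
TIGIT
BTLA
VSIR
ENTPD1
NT5E
ACE
ACE2
ANPEP
DPP4
MME
CD248
ENG
TEK
TIE1
ESAM
PECAM1
CDH13
DSG2
DSG3
DSC2
PVR
NECTIN1
NECTIN2
EFNA1
EFNA5
GJA1
CX3CR1
CXCR4
CCR5
CCR7
S1PR1
GPR37
ADGRE5
ADGRL1
CELSR1
FZD7
LRP5
PTPRC
PTPRJ
PTPRM
PTPRF
CD99
BST2
LY75
LY6E
TSPAN8
EMP2
GPC3
SDC4
GYPA
GYPC
SLC2A1
SLC7A5
SLC6A4
ATP2B1
KCNJ2
SCN1A
TRPV1
P2RX7
P2RY12
ADORA2A
GABBR1
GRIN1
CHRNA7
ERBB3
ERBB4
HBEGF
TGFBR1
TGFBR2
ACVR1
BMPR1A
BMPR2
AMHR2
GHR
PRLR
EPOR
MPL
LEPR
INSR
IGF2R
TNFRSF11A
TNFRSF11B
TNFRSF13B
TNFRSF13C
TNFRSF17
CD79A
CD79B
MS4A1
CR1
CR2
C3AR1
C5AR1
CFH
THBD
PROCR
F2R
F2RL1
GP1BA
GP5
GP9
ITGA2B
VWF
CLEC4C
CLEC7A
CLEC9A
OLR1
TREM1
TREM2
CD68
CD93
CD164
MCAM
BCAM
CEACAM1
CEACAM6
CEACAM8
PSG1
HLA-A
HLA-B
HLA-C
HLA-E
HLA-F
HLA-G
B2M
MICA
MICB
RAET1E
ULBP1
ULBP2
ULBP3
SFGS0001
SFGS0002
SFGS0003
SFGS0004
SFGS0005
SFGS0006
SFGS0007
SFGS0008
SFGS0009
SFGS0010
SFGS0011
SFGS0012
SFGS0013
SFGS0014
SFGS0015
SFGS0016
SFGS0017
SFGS0018
SFGS0019
SFGS0020
SFGS0021
SFGS0022
SFGS0023
SFGS0024
SFGS0025
SFGS0026
SFGS0027
SFGS0028
SFGS0029
SFGS0030
SFGS0031
SFGS0032
SFGS0033
SFGS0034
SFGS0035
SFGS0036
SFGS0037
SFGS0038
SFGS0039
SFGS0040
SFGS0041
SFGS0042
SFGS0043
SFGS0044
SFGS0045
SFGS0046
SFGS0047
SFGS0048
SFGS0049
SFGS0050
SFGS0051
SFGS0052
SFGS0053
SFGS0054
SFGS0055
SFGS0056
SFGS0057
SFGS0058
SFGS0059
SFGS0060
SFGS0061
SFGS0062
SFGS0063
SFGS0064
SFGS0065
SFGS0066
SFGS0067
SFGS0068
SFGS0069
SFGS0070
SFGS0071
SFGS0072
SFGS0073
SFGS0074
SFGS0075
SFGS0076
SFGS0077
SFGS0078
SFGS0079
SFGS0080
SFGS0081
SFGS0082
SFGS0083
SFGS0084
SFGS0085
SFGS0086
SFGS0087
SFGS0088
SFGS0089
SFGS0090
SFGS0091
SFGS0092
SFGS0093
SFGS0094
SFGS0095
SFGS0096
SFGS0097
SFGS0098
SFGS0099
SFGS0100
SFGS0101
SFGS0102
SFGS0103
SFGS0104
SFGS0105
SFGS0106
SFGS0107
SFGS0108
SFGS0109
SFGS0110
SFGS0111
SFGS0112
SFGS0113
SFGS0114
SFGS0115
SFGS0116
SFGS0117
SFGS0118
SFGS0119
SFGS0120
SFGS0121
SFGS0122
SFGS0123
SFGS0124
SFGS0125
SFGS0126
SFGS0127
SFGS0128
SFGS0129
SFGS0130
SFGS0131
SFGS0132
SFGS0133
SFGS0134
SFGS0135
SFGS0136
SFGS0137
SFGS0138
SFGS0139
SFGS0140
SFGS0141
SFGS0142
SFGS0143
SFGS0144
SFGS0145
SFGS0146
SFGS0147
SFGS0148
SFGS0149
SFGS0150
SFGS0151
SFGS0152
SFGS0153
SFGS0154
SFGS0155
SFGS0156
SFGS0157
SFGS0158
SFGS0159
SFGS0160
SFGS0161
SFGS0162
SFGS0163
SFGS0164
SFGS0165
SFGS0166
SFGS0167
SFGS0168
SFGS0169
SFGS0170
SFGS0171
SFGS0172
SFGS0173
SFGS0174
SFGS0175
SFGS0176
SFGS0177
SFGS0178
SFGS0179
SFGS0180
SFGS0181
SFGS0182
SFGS0183
SFGS0184
SFGS0185
SFGS0186
SFGS0187
SFGS0188
SFGS0189
SFGS0190
SFGS0191
SFGS0192
SFGS0193
SFGS0194
SFGS0195
SFGS0196
SFGS0197
SFGS0198
SFGS0199
SFGS0200
SFGS0201
SFGS0202
SFGS0203
SFGS0204
SFGS0205
SFGS0206
SFGS0207
SFGS0208
SFGS0209
SFGS0210
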