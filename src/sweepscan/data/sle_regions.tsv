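name	chrom	pos_mb
C1q	1	22.96
IL12RB2	1	67.55
PTPN22	1	114.16
FCGR2A,FCGR3A	1	159.74
TNFSF4	1	171.42
NMNAT2	1	181.48
NCF2	1	181.79
APOBEC4	1	181.88
CFH	1	194.89
CFHR1,CFHR4	1	196.79
CRP	1	199.72
IL10	1	205.01
LYST	1	233.89
RASGRP3	2	33.51
TET3,DGUOK	2	74.21
IFIH1	2	162.83
STAT4	2	191.60
PDCD1	2	242.44
SCN10A	3	38.71
TREX1	3	48.48
DNASE1L3	3	58.15
PXK	3	58.29
TMEM39A	3	120.63
CD80	3	120.73
AFF1	4	88.15
BANK1	4	102.93
LEF1	4	109.19
IL21	4	123.75
PPP2CA	5	133.53
TNIP1	5	150.39
PTTG1	5	159.78
C4	6	32.09
HLA-DRB1	6	32.59
ITPR3	6	33.70
UHRF1BP1	6	34.87
BACH2	6	90.69
ATG5,PRDM1	6	106.53
TNFAIP3	6	138.23
ICA1	7	8.12
JAZF1	7	27.84
IKZF1	7	50.31
IRF5,TNPO3	7	128.37
XKR6	8	10.79
BLK	8	11.39
LYN	8	56.95
ARMC3	10	23.26
LRRC18,WDFY4	10	49.89
ARID5B,RTKN2	10	63.94
SLC29A3	10	72.75
PHRF1,IRF7	11	0.58
CD44,PDHX	11	34.94
DDX6	11	118.13
ETS1	11	127.83
CREBL2,GPR19,CDKN1B	12	12.66
DRAM1	12	102.27
SLC15A4	12	127.84
ELF1	13	40.40
C2	14	20.75
CSK	15	72.86
DNASE1	16	3.64
CLEC16A	16	11.04
PRKCB	16	23.75
SEZ6L2	16	29.79
ITGAM,ITGAX	16	31.18
IRF8	16	84.49
IKZF3,ZPBP2	17	37.91
CD226	18	65.68
TYK2	19	10.32
ICAM1,ICAM4,ICAM5	19	10.40
ACP5	19	11.55
DDA1	19	17.28
UBE2L3	22	20.25
SCUBE1	22	41.93
IRAK1,MECP2	X	152.93
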