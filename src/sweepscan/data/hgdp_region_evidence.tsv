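region	chrom	center_mb	neglogp_fst	neglogp_fst_pop	neglogp_ihs	neglogp_ihs_pop	neglogp_xpehh	neglogp_xpehh_pop
PTPN22	1	114.158	2.5	global	3.0	Afr	3.5	Afr
TNFSF4	1	171.419	4.5	global	2.5	EAsia	3.5	EAsia
CRP	1	199.719	3.5	global	NA	NA	2.5	Afr;Eur
IL10	1	205.008	4.0	global	2.0	MEast;EAsia	2.5	SAsia;EAsia
TET3,DGUOK	2	74.212	2.5	global	2.0	SAsia	3.5	MEast;SAsia
TNIP1	5	150.390	3.5	global	1.5	MEast	3.0	Amer
PTTG1	5	159.781	NA	NA	3.5	Afr	2.8	MEast;Afr
UHRF1BP1	6	34.868	NA	NA	3.0	Amer	3.5	Amer
IKZF1	7	50.315	3.5	global	3.0	EAsia	2.5	EAsia
BLK	8	11.389	4.0	global	3.0	SAsia;MEast;Afr	4.0	EAsia
ARMC3	10	23.257	2.5	global	2.5	MEast	3.5	MEast
SLC15A4	12	127.844	3.5	global	NA	NA	2.5	Afr;Eur
CLEC16A	16	11.038	2.0	global	4.0	Amer	4.0	Amer
ITGAM	16	31.179	2.5	global	2.0	EAsia	3.5	EAsia
IRF8	16	84.490	2.5	global	2.0	SAsia	4.0	SAsia
SCUBE1	22	41.929	2.5	global	2.0	Oceania	3.0	Oceania
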