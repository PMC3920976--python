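region	chrom	center_mb	neglogq_ihs	neglogq_ihs_pop	neglogq_tajd	neglogq_tajd_pop	neglogq_fst	neglogq_fst_pop	top1_fst_value	top1_fst_pair	min_gene_p	min_gene_p_pop
PTPN22	1	114.158	NA	NA	3.6	YRI	3.2	NA	0.75	YRI-ASN	NA	NA
TNFSF4	1	171.419	2.5	ASN	2.3	ASN	2.7	NA	0.60	YRI-ASN	0.005	ASN
NMNAT2	1	181.484	2.5	ASN	2.4	CEU	NA	NA	NA	NA	0.004	ASN
NCF2	1	181.791	2.5	ASN	NA	NA	NA	NA	0.65	CEU-YRI	0.004	ASN
APOBEC4	1	181.882	2.5	ASN	NA	NA	NA	NA	0.65	CEU-YRI	0.004	ASN
CFH	1	194.888	NA	NA	NA	NA	3.0	NA	0.60	YRI-ASN	NA	NA
CFHR1,CFHR4	1	196.789	2.0	YRI	NA	NA	3.0	NA	0.60	YRI-ASN	NA	NA
TET3,DGUOK	2	74.212	2.7	CEU	2.6	ASN	3.2	NA	0.85	YRI-ASN	0.001	CEU
IFIH1	2	162.832	NA	NA	3.8	CEU	2.2	NA	0.78	CEU-YRI	NA	NA
TREX1	3	48.481	2.4	ASN	2.1	ASN	NA	NA	NA	NA	0.002	ASN
TNIP1	5	150.390	NA	NA	3.0	CEU	NA	NA	0.65	NA	NA	NA
ITPR3	6	33.697	3.4	YRI	3.3	YRI	3.3	NA	0.60	YRI-ASN	NA	NA
UHRF1BP1	6	34.868	2.5	CEU	2.4	YRI	NA	NA	0.50	NA	0.004	CEU
XKR6	8	10.791	2.7	ASN	3.3	ASN	2.6	NA	0.92	YRI-ASN	0.003	ASN
BLK	8	11.389	2.7	ASN	3.2	ASN	2.6	NA	0.92	YRI-ASN	0.005	ASN
ARMC3	10	23.257	NA	NA	2.5	CEU	2.5	NA	0.65	YRI-ASN	NA	NA
LRRC18,WDFY4	10	49.893	NA	NA	2.0	ASN	2.5	NA	0.80	YRI-ASN	NA	NA
ITGAM	16	31.179	NA	NA	NA	NA	3.4	NA	0.75	YRI-ASN	NA	NA
CD226	18	65.681	NA	NA	3.1	CEU	3.7	NA	0.80	CEU-YRI	NA	NA
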