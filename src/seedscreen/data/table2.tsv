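seed	seed_length	size	nes	fwer_p
TAATAA	6	70	2.691	0
ACTTGA	6	14	2.674	0
CCTTAA	6	16	2.642	0
AATTAA	6	44	2.567	0
ACTGGA	6	10	2.510	0
TAGGAA	6	13	2.505	0
TAAAGA	6	20	2.482	0.002
GAATAA	6	21	2.474	0.002
AAGTTA	6	20	2.426	0.004
TCACAA	6	12	2.413	0.005
AAATGA	6	21	2.405	0.005
AGATCA	6	35	2.378	0.006
TTATAA	6	22	2.335	0.009
AATATT	6	15	2.314	0.015
AGATCT	6	17	2.304	0.015
TGAATA	6	16	2.255	0.026
CTGGAA	6	8	2.198	0.047
CAATTAA	7	18	2.911	0.000
GAGATCA	7	18	2.387	0.001
GAAAGAA	7	10	2.241	0.015
TTAATAA	7	17	2.227	0.015
GTATTTA	7	16	2.211	0.016
ATAGGAA	7	6	2.187	0.021
ACCTTAA	7	8	2.185	0.021
TAATTAA	7	8	2.179	0.024
TTAATTA	7	10	2.151	0.037
ACAATTA	7	10	2.148	0.039
AAGATCA	7	13	2.140	0.041
CTAATAA	7	20	2.139	0.041
CTAATTA	7	7	2.136	0.043
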