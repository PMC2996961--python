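transcript	symbol	score	hexamer	heptamer	status	enriched_flag
NM_003217	TEGT	3.51	CAAGGT	TCAAGGT	OTE	+
NM_016368	ISYNA1	3.43	TGTCCA	GTGTCCA	OTE	*
NM_001240	CCNT1	3.28	CAAGGT	TCAAGGT	OTE	+
NM_002197	ACO1	3.11	ACTTGA	CACTTGA	Unconfirmed	+
NM_003947	HAPIP	2.88	ACTTGA	TACTTGA	OTE	+
NM_002337	LRPAP1	2.8	TCACAA	ATCACAA	OTE	+
NM_005799	INADL	2.76	ACTTGA	AACTTGA	OTE	+
NM_003554	OR1E2	2.72	TTGTAA	TTTGTAA	Unconfirmed	-
NM_013345	GPR132	2.68	AGATCA	GAGATCA	Unconfirmed	+
NM_004584	RAD9A	2.65	TAAGGA	CTAAGGA	OTE	-
NM_003266	TLR4	2.64	AAAGTT	CAAAGTT	Unconfirmed	-
NM_000674	ADORA1	2.63	TAATAA	CTAATAA	OTE	+
NM_002382	MAX	2.57	AAGAAA	TAAGAAA	Hit	-
NM_006986	MAGED1	2.56	ACTTGA	AACTTGA	False +ve	+
NM_000875	IGF1R	2.55	CACTTA	ACACTTA	Hit	-
NM_016953	PDE11A	2.54	GTAAGA	GGTAAGA	Hit	-
NM_014379	KCNV1	2.54	TGTCCA	GTGTCCA	False +ve	*
NM_080674	C20orf86	2.52	CGTTGT	GCGTTGT	False +ve	-
NM_002467	MYC	2.51	TTACAC	GTTACAC	Hit	+
XM_497793	LOC402037	2.51	GCATTA	GGCATTA	False +ve	-
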