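locus	gene	sequence	position
LSA0123	lsa0123	TGAAAGCGTTACAA	-93
LSA0185	galP	GAACATCGTTATCA	-46
LSA0200	rbsU	GTAAACCGTTTTCA	-113
LSA0254	lsa0254	TGTAAGCGTTTTAT	-56
LSA0289	xpk	CTATTACGATGACA	-8
LSA0292	budC	TGTAACCGTTTTAA	-51
LSA0353	lsa0353	AGAAAGCGCTTATA	-102
LSA0370	arcA	TGAAAGCGATTACC	-58
LSA0449	manL	TGTTAGCGTTTTTA	-56
LSA0533	iunH2	AAAAAGCGTTCACA	-35
LSA0572	tdcB	TGAAAACGTTCTAA	-134
LSA0608	gloAN	TGTAACCGTTTTAA	-100
LSA0649	glpK	AGGAAACGTTTTCC	-42
LSA0664	loxL1	AGAAAGCGAGTACA	-82
LSA0764	galK	TGAAAGCGATTAAT	-30
LSA0795	deoC	TGAAAGCGTTAACA	-33
LSA0974	pflB	TACGAACGCTTACA	-147
LSA1048	fruR	TGTAAACGATGACA	-39
LSA1141	ppdK	GGTTATCGATAAAA	-29
LSA1146	manA	CGAAATCGCTTTAA	-98
LSA1188	pox1	TGTAATCGATTTCA	-88
LSA1204	lsa1204	TGTAATCGTTTTTT	-127
LSA1343	eutD	GTAAAACGCTCTCA	-94
LSA1399	loxL2	TGTAAACGATTTCA	-42
LSA1457	lsa1457	TGATAACGCTTACA	-85
LSA1463	ptsH	TGAAAGCGGTATAG	-161
LSA1641	nanE	TGTAAGCGGTTAAT	-85
LSA1643	lsa1643	TGATAACGCTTACA	-31
LSA1651	lsa1651	GGTAAGCGGTTAAA	-148
LSA1711	lacL	TGAAACCGTTTTAA	-36
LSA1792	scrA	TGTAAACGGTTGTA	-78
LSA1830	pox2	TTGTAACGCTTACA	-70
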