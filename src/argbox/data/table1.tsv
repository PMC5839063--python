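gene_code	gene_name	box_id	sequence	left	right	distance	ri	flags
SCO0256		AB.SCO0256_1	GCCCGCACGCTGTTGGGCAG	245912	245931	55	5.8	af
SCO0256		AB.SCO0256_2	CACCGCACGAGAGCGCGGAG	245932	245951	35	7.7	af
SCO1086		AB.SCO1086_1	CAGTCAATGACTTTTCAGGT	1146431	1146450	5	5.0	a
SCO1086		AB.SCO1086_2	GAACGCATACCTATGCAGTG	1146451	1146470	25	15.7	
SCO1236	ureA	AB.SCO1236_0	GATTGATTACCGATGCAGTC	1310778	1310797	183	7.4	
SCO1483	pyrA	AB.SCO1483_0	GGTCGAACAGGTAGGCGGCG	1587621	1587640	209	5.6	c
SCO1487	pyrB	AB.SCO1487_0	CTCCGTAAGGCGATTCATGC	1591396	1591415	9	9.3	
SCO1488	pyrR	AB.SCO1488_0	TGTTGCTTGTCCATACGAAA	1592070	1592089	-13	7.4	
SCO1489	bldD	AB.SCO1489_0	CGCTGCGTAACCTCACAGTG	1592299	1592318	63	9.6	
SCO1570	argH	AB.SCO1570_1	TCATGCATGAGTATGCAGAA	1681889	1681908	30	16.3	a
SCO1570	argH	AB.SCO1570_2	CTCTGCATGTTTCGTCAATC	1681909	1681928	50	4.4	
SCO1580	argC	AB.SCO1580_A0	GCCCGCATACCCACTCGCTC	1691417	1691436	-44	9.5	c
SCO1580	argC	AB.SCO1580_B1	GAGAGCATGACTATACGTGC	1691479	1691498	18|-3	9.1	ad
SCO1580	argC	AB.SCO1580_B2	CGATGCACGTTTATGCAATG	1691499	1691518	38|-23	13.3	d
SCO1864		AB.SCO1864_0	ATTCGTAACCCCATCCGGCG	1998411	1998430	38	3.8	ce
SCO2015		AB.SCO2015_0	CCACGCATGACCACTCAACA	2157812	2157831	159	11.4	
SCO2055		AB.SCO2055_1	GTTCGGACGGTCACGCAGTG	2202678	2202697	63	11.8	b
SCO2055		AB.SCO2055_2	GCATGAACGGTTGTACGAAG	2202699	2202718	42	9.0	
SCO2231-2	malE-R	AB.SCO2231-2_A1	TGCTGCAAAAATGTGCAAGA	2400395	2400414	136|237	10.7	b
SCO2231-2	malE-R	AB.SCO2231-2_A2	ATCTCCGAAGTTATCCGGGC	2400416	2400435	157|216	5.1	
SCO2231-2	malE-R	AB.SCO2231-2_B0	CTCTGCAAGCTCTTGCCGCC	2400507	2400526	248|125	11.9	
SCO2529	smpA	AB.SCO2529_0	GTCCGTATCAGTATGCGGGA	2727401	2727420	144	10.7	
SCO2686		AB.SCO2686_A1	TATTGAGCGTCCTTTCAAAA	2930741	2930760	-98	5.5	bcf
SCO2686		AB.SCO2686_A2	TCGCGCATAGAAGTGCAGTC	2930762	2930781	-77	7.3	cf
SCO2686		AB.SCO2686_B0	CAATGCATGATCATGCCACA	2930862	2930881	23	12.6	f
SCO3034	whiB	AB.SCO3034_0	GGAACCAAGCCCATGCAGTA	3321156	3321175	140	9.4	f
SCO3067	arsI|sigI	AB.SCO3067_0	CACAGAACACACTTGCGGTC	3360549	3360568	108|126	7.6	f
SCO3943	rstP	AB.SCO3943_A0	GGACGCATATGCACGCGTTG	4339185	4339204	39	10.2	bf
SCO3943	rstP	AB.SCO3943_B0	TTCTGCAAGATCATTAATGC	4339215	4339234	69	9.4	bf
SCO3978-9		AB.SCO3978-9_0	TAACGGATAGCTTTTCATAA	4381976	4381995	27|35	9.2	f
SCO4158		AB.SCO4158_0	CCTTGGATGACCTTGCGCCC	4576182	4576201	48	11.3	f
SCO4293		AB.SCO4293_0	GCCTCCATGGCTGTGCAGAC	4708595	4708614	-7	14.5	f
SCO4425	afsS	AB.SCO4425_0	TGCCGGACGGGCGCGCGGAG	4842637	4842656	64	8.8	
SCO4426	afsR	AB.SCO4426_0	TTTGCCTTGTTCATGCCGAC	4845804	4845823	36	1.2	cf
SCO5226	nrdA	AB.SCO5226_0	GACTGGACAGGCGTGCGCGC	5688301	5688320	158	9.2	f
SCO5326-7		AB.SCO5326-7_0	GCCTCGTTGGTCATGCATCC	5796724	5796743	146|-7	8.9	f
SCO5583	amtB	AB.SCO5583_0	CCATGCCAGGTCATTCGGAG	6085777	6085796	235	10.2	
SCO5864		AB.SCO5864_0	CTCTCCGTGATCATGCACCC	6421332	6421351	267	11.8	f
SCO5896	redH	AB.SCO5896_0	GACGGCGTGGGCCTGCAGAA	6461067	6461086	-1669	6.3	c
SCO5976	arcB	AB.SCO5976_1	CGCTGTATAGAAATTCAGAA	6550325	6550344	55	8.2	a
SCO5976	arcB	AB.SCO5976_2	GTTCGTATAGACTTCCAGAA	6550345	6550364	35	9.6	
SCO7036	argG	AB.SCO7036_1	CTTTGCATGGTCATGCGTAA	7824734	7824753	18	17.2	a
SCO7036	argG	AB.SCO7036_2	TGATGCATACTCTTCCTATG	7824754	7824773	-2	8.1	
SCO7314	sigM	AB.SCO7314_0	ATCCGCATGCTCATAGAAAC	8120535	8120554	-13	9.5	
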