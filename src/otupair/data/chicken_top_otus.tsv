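otu_id	isolate	accession	similarity	pct_cecal	pct_fecal
4	Bacteroides fragilis	CR626927	99.62	14.1	1.2
1	Lactobacillus crispatus	Y17362	99.81	11.3	15.4
2	Lactobacillus johnsonii	ACGR01000047	99.61	9.6	12.2
3	Lactobacillus salivarius	AF089108	99.43	5.4	12.7
5	Lactobacillus reuteri	AP007281	99.40	4.3	5.6
8	Acholeplasma palmae	L33734	79.53	3.9	0.5
133	Lactobacillus helveticus	ACLM01000202	97.62	3.5	8.6
9	Butyricicoccus pullicaecorum	EU410376	82.18	3.4	0.2
12	Faecalibacterium prausnitzii	AJ413954	94.71	2.3	0.3
10	Lactobacillus vaginalis	AF243177	99.60	1.3	0.8
874	Lactobacillus helveticus	ACLM01000202	96.67	1.2	2.7
13	Pontibacillus litoralis	EU583724	78.46	0.9	0.2
14	Exiguobacterium acetylicum	X70313	78.33	0.9	0.1
21	Ruminococcus albus	L76598	82.62	0.9	0.1
16	Ruminococcus albus	L76598	89.88	0.8	0.1
18	Parabacteroides distasonis	CP000140	97.31	0.8	0.0
15	Ruminococcus flavefaciens	X83430	86.85	0.8	0.1
17	Clostridium cellobioparum	X71856	83.27	0.7	0.1
23	Clostridium termitidis	FR733680	80.37	0.7	0.1
25	Clostridium symbiosum	M59112	91.97	0.7	0.1
6	Clostridium perfringens	CP000246	99.60	0.1	4.5
2234	Lactobacillus crispatus	Y17362	91.98	0.3	2.9
7	Clostridium lituseburense	M59107	96.91	0.4	2.8
2200	Lactobacillus salivarius	AF089108	93.01	0.3	2.8
11	Candidatus Arthromitus sp.	X80834	100.00	0.0	2.1
1905	Lactobacillus salivarius	AF089108	94.44	0.1	2.1
1845	Lactobacillus crispatus	Y17362	94.50	0.1	1.2
2251	Lactobacillus johnsonii	ACGR01000047	89.41	0.2	1.2
2154	Lactobacillus pontis	AJ422032	92.01	0.1	1.0
254	Lactobacillus helveticus	ACLM01000202	98.59	0.2	0.9
1557	Lactobacillus crispatus	Y17362	93.60	0.1	0.7
1814	Lactobacillus gallinarum	AJ417737	90.77	0.1	0.6
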