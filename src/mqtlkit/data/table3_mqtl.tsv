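mqtl_id	trait_class	chromosome	ci_left	ci_right	width_cM	n_qtls	components	n_populations	n_markers	n_genes	candidate_genes
1	GY	1B	73.44	81.62	8.18	5	Tn, TKW	4	1138	641	OsUGE1
2	GY	1D	134.90	172.00	37.10	4	Th, TKW, GrN	3	707	403	Adh;ATPase
3	GY	2A	132.85	148.56	15.71	5	Th, TKW, GrN	4	270	334
4	GY	2B	82.27	95.76	13.49	6	Th, TKW	3	669	652	GIF1;crp1
5	GY	2D	51.79	67.70	15.91	13	Th, TKW, GrN, HI	3	676	55	PpdD1
6	GY	2D	129.37	168.19	38.82	6	Th, TKW, GrN	4	1777	772	Compact spike gene;3 pistils per floret;Prog1
7	GY	3B	58.72	86.04	27.32	6	Th, TKW, GrN	4	1537	1666	Brittle rachis 3;ATPase;Gn1-a;NYC1
8	GY	3B	159.98	207.40	47.42	4	TKW, GrN	3	1804	408	Phytoclock1 (GARP protein)
9	GY	3D	84.21	102.07	17.86	7	Th, TKW, GrN, SL	5	1048	1070	GoGat;Lsk1
10	GY	4A	100.12	139.38	39.26	8	Th, TKW, GrN, Tn, SL	3	140	165	SRS5
11	GY	4B	82.87	89.88	7.02	12	Th, TKW, GrN, SL	7	939	608	Gibberellin response modulator;emp4
12	GY	5A	42.68	74.25	31.57	4	Th, TKW	3	4145	1772	DEP1
13	GY	5A	158.70	182.55	23.85	6	Th, TKW, GrN, HI	4	300	190	C17648
14	GY	5B	188.35	214.46	26.12	5	Th, TKW	3	1411	108	OsNaPRT1
15	GY	6A	79.93	108.72	28.80	5	Th, TKW	4	1369	1989	TOC I;Cry2;Gw2;FUWA;EP3;GS2
16	GY	6B	100.39	106.93	6.54	3	Th, TKW, SL	3	114	46
17	GY	7A	78.75	106.12	27.37	7	Th, TKW, GrN	4	400	162	incw2;MOC1;SSG6
18	GY	7D	92.09	97.63	5.54	7	Th, TKW, GrN	5	263	30	Rc3
19	GPC	1A	48.66	75.55	26.89	2	GPC	2	1847	548	GliA3;Tri
20	GPC	2A	93.52	106.85	13.33	3	GPC	2	1084	306	RuBisCO
21	GPC	2B	68.01	73.84	5.83	5	GPC	3	488	131
22	GPC	2D	103.52	117.20	13.69	6	GPC	2	268	65
23	GPC	3A	65.43	71.33	5.90	8	GPC	2	470	476	Vivip-1
24	GPC	4A	72.15	95.71	23.56	3	GPC	2	240	37
25	GPC	6B	88.17	94.87	6.70	4	GPC	3	472	30
26	GPC	7A	156.71	171.82	15.11	3	GPC	2	164	17
27	BQ	1A	75.55	88.69	13.15	5	W, Vol	3	3294	2334	GluA1
28	BQ	1B	84.81	99.54	14.74	7	Visco, Fsw, Msap	2	358	152
29	BQ	1B	124.80	135.99	11.19	4	Visco, W	2	147	33
30	BQ	3D	134.45	138.23	3.78	5	Visco, W, Panif	2	23	33
31	BQ	4B	79.14	85.97	6.83	3	W, Fsta	2	540	230
32	BQ	7A	194.75	204.32	9.57	4	Vol, Pelsc, Tst	3	528	309
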