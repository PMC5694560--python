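chromosome	SNP	SSR	RFLP	DarT	Gene
1A	6002	268	112	121	23
1B	8336	311	139	169	31
1D	3795	193	94	57	16
2A	6148	224	129	75	16
2B	8837	223	119	163	24
2D	6950	209	110	68	16
3A	6284	199	105	97	8
3B	8115	333	114	387	17
3D	6585	154	81	45	7
4A	5597	226	104	113	11
4B	4566	136	63	46	7
4D	3143	86	61	15	1
5A	7012	182	91	54	9
5B	8077	260	100	135	12
5D	5996	142	53	26	9
6A	5242	187	86	87	7
6B	6258	226	107	135	8
6D	4120	128	72	28	5
7A	7336	263	109	183	22
7B	7496	277	106	179	13
7D	5537	140	46	48	22
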