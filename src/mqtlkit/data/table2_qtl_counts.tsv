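population_id	parent1	parent2	size	design	lines	Th	TKW	Tn	GrN	HI	PH	SL	GrW	Visco	W	Vol	OtherBQ	GPC
P01	Apache	Ornicar	222	DH	176	12	0	0	0	0	0	0	0	0	0	0	0	20
P02	Courtot	Chinese Spring	187	DH	662	0	7	0	0	0	0	0	0	8	5	0	10	0
P03	Opata 85	W7984	114	RILs	511	0	11	0	10	0	0	0	17	0	0	0	0	2
P04	Opata 85	W7984	110	RILs	358	0	0	0	0	0	2	0	0	0	0	0	0	0
P05	WL711 and HD2329	PH132 and PH133	100	RILs/NILs	78	0	0	0	0	0	0	0	0	0	0	0	0	13
P06	W7984	Prinz	72	BC2F3	210	11	8	8	0	0	0	0	0	0	0	0	0	0
P07	Renan	Recital	194	RILs	212	1	5	0	0	0	0	0	0	0	7	3	2	11
P08	Avalon	Habbit	200	RILs	60	0	0	0	0	0	0	0	0	0	0	0	0	7
P09	Flair	XX86	111	BC2F3	197	9	14	2	8	0	0	0	5	0	0	0	0	0
P10	RL4452	AC Domain	182	DH	322	3	0	0	0	0	0	0	0	0	5	5	6	8
P11	AC Karma	87E03-S2B1	414	DH	489	3	3	0	0	0	2	0	0	0	0	0	0	0
P12	Karl 92	TA 4152-4	190	BC2F1	666	2	0	1	1	0	0	0	0	0	0	0	0	0
P13	Arche	Recital	222	DH	200	11	0	0	0	0	0	0	0	1	16	0	5	21
P14	Opata85	W7984	110	RILs	521	3	0	5	6	2	0	0	0	0	0	0	0	0
P15	WL711	PH132	110	RILs	173	2	0	1	0	0	0	0	0	0	0	0	0	0
P16	Chuan 35050	Shannong 483	131	RILs	404	0	2	0	1	0	0	0	0	0	0	0	0	0
P17	Superb	BW278	402	DH	268	1	1	0	0	3	0	0	0	0	0	0	0	0
P18	TA4152-60	ND495	120	DH	746	0	0	0	0	0	2	2	0	0	0	0	0	0
P19	Chuan 35050	Shannong 483	131	RILs	381	0	4	0	1	0	0	0	0	0	0	0	0	0
P20	Heshangmai9	Yu8679	142	RILs	1142	0	4	0	0	0	2	0	0	0	0	0	0	0
P21	Halberd	Cutter	64	RILs	700	0	1	0	2	0	0	0	0	0	0	0	0	0
P22	Chuanmai42	Chuannong16	127	F2	1912	0	2	0	1	0	0	0	0	0	0	0	0	0
P23	Laizhou953	Am3	166	RILs	857	0	0	0	1	0	0	1	0	0	0	0	0	0
P24	Line3228	Jing 4839	237	F2	1125	0	3	0	2	0	0	4	0	0	0	0	0	0
P25	RAC875	Kukri	368	DH	850	1	2	0	0	0	0	0	0	0	0	0	0	0
P26	Rye Selection111	Chinese Spring	230	RILs	836	0	2	0	0	0	0	0	0	0	0	0	0	0
P27	Hanxuan10	Lumai 14	150	DH	395	1	0	0	0	0	0	0	0	0	0	0	0	0
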