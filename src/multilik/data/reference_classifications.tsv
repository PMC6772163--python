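# Published multifactorial likelihood classifications (Likely) Pathogenic set.
# Component LRs are printed at 2 decimal places; combined_lr and posterior are
# the published values computed from unrounded components.
gene	hgvs_c	hgvs_p	prior	lr_segregation	lr_pathology	lr_cooccurrence	lr_family_history	combined_lr	posterior	iarc_class
BRCA1	c.131G>T	p.(Cys44Phe)	0.81	156.17	41.24	.	.	6440.72	1.000	P
BRCA1	c.135-1G>T	.	0.97	9528.00	2.01	.	.	19140.38	1.000	P
BRCA1	c.140G>A	p.(Cys47Tyr)	0.81	13545.00	60.31	.	.	816898.95	1.000	P
BRCA1	c.191G>A	p.(Cys64Tyr)	0.81	5300394.00	189.09	.	.	1002254925.72	1.000	P
BRCA1	c.211A>G	p.(Arg71Gly)	0.81	383.27	.	.	.	383.27	0.999	P
BRCA1	c.212+1G>A	.	0.97	1794.18	3.73	.	.	6692.28	1.000	P
BRCA1	c.212+1G>T	.	0.97	7.65	3.34	.	.	25.56	0.999	P
BRCA1	c.213-12A>G	.	0.97	29429.38	1132.14	.	.	33318129.21	1.000	P
BRCA1	c.302-2del	.	0.97	58263.44	387.67	1.43	1.87	60436990.13	1.000	P
BRCA1	c.3G>T	p.(Met1?)	0.96	1.97	3.73	.	.	7.36	0.994	P
BRCA1	c.4097-2A>G	.	0.97	0.42	9.99	.	.	4.20	0.993	P
BRCA1	c.4185+2_4185+22delinsA	.	0.96	0.33	30.65	1.26	28.61	358.47	1.000	P
BRCA1	c.4185G>A	p.(=)	0.97	39.32	13.91	.	.	547.01	1.000	P
BRCA1	c.4357+1G>T	.	0.97	0.67	.	1.14	6.63	5.10	0.994	P
BRCA1	c.4484+1del	.	0.97	0.33	28.14	.	.	9.22	0.997	P
BRCA1	c.4484G>C	p.(Arg1495Thr)	0.34	27.73	9.99	.	.	276.94	0.993	P
BRCA1	c.4485-1G>T	.	0.97	.	.	1.03	11.76	12.15	0.997	P
BRCA1	c.4675+3A>T	.	0.97	.	.	1.03	4.18	4.31	0.993	P
BRCA1	c.4675G>A	p.(Glu1559Lys)	0.97	1.79	.	1.26	3.48	7.84	0.996	P
BRCA1	c.4676-1G>A	.	0.97	3.75	.	2.92	32.31	353.30	1.000	P
BRCA1	c.4986+6T>G	.	0.97	18.94	1134.07	.	.	21484.60	1.000	P
BRCA1	c.4987-2A>G	.	0.97	1.99	9.70	1.05	.	20.20	0.998	P
BRCA1	c.5062_5064del	p.(Val1688del)	0.66	16.93	.	1.18	13.41	267.23	0.998	P
BRCA1	c.5074+1G>T	.	0.97	13.92	1.69	1.10	1.18	30.64	0.999	P
BRCA1	c.5074+2T>C	.	0.97	2.43	3.73	1.07	7.31	70.75	1.000	P
BRCA1	c.5074G>C	p.(Asp1692His)	0.97	1.91	3.73	1.25	0.90	8.02	0.996	P
BRCA1	c.5089T>C	p.(Cys1697Arg)	0.81	730.63	2.41	.	.	1758.02	1.000	P
BRCA1	c.5144G>A	p.(Ser1715Asn)	0.66	57.86	3.73	1.30	3.63	1016.90	0.999	P
BRCA1	c.5153-1G>A	.	0.97	.	.	1.22	3.11	3.78	0.992	P
BRCA1	c.5277+1_5277+6del	.	0.97	.	.	1.03	15.10	15.60	0.998	P
BRCA1	c.53T>C	p.(Met18Thr)	0.66	1.84	5.28	1.22	25.48	300.74	0.998	P
BRCA1	c.5468-1G>A	.	0.97	2.10	41.24	1.03	1.24	110.47	1.000	P
BRCA1	c.547+1G>T	.	0.97	1.95	1.67	.	.	3.25	0.991	P
BRCA1	c.5509T>C	p.(Trp1837Arg)	0.81	183.54	0.73	1.14	0.19	28.33	0.992	P
BRCA1	c.5516T>C	p.(Leu1839Ser)	0.66	21.96	51.90	.	.	1139.69	1.000	P
BRCA1	c.81-9C>G	.	0.97	.	.	1.07	8.13	8.67	0.996	P
BRCA2	c.(?_-227)_67+?del	p.?	0.96	13.34	1.17	.	.	15.56	0.997	P
BRCA2	c.3G>A	p.(Met1?)	0.96	67.62	2.17	1.07	.	157.49	1.000	P
BRCA2	c.475+1G>T	.	0.97	1.90	.	1.21	9.19	21.21	0.999	P
BRCA2	c.517-2A>G	.	0.97	3.50	3.82	1.28	3.12	53.08	0.999	P
BRCA2	c.631+2T>G	.	0.97	22.51	0.81	.	.	18.28	0.998	P
BRCA2	c.632-1G>A	.	0.97	95.33	2.21	.	.	210.58	1.000	P
BRCA2	c.632-2A>G	.	0.97	152.33	0.79	1.05	0.18	23.32	0.999	P
BRCA2	c.632-3C>G	.	0.97	.	.	1.05	3.60	3.78	0.992	P
BRCA2	c.67+1G>T	.	0.97	3.91	1.19	1.05	1.48	7.21	0.996	P
BRCA2	c.6938-2A>G	.	0.97	.	.	1.08	5.30	5.70	0.995	P
BRCA2	c.7007G>A	p.(Arg2336His)	0.34	48.57	0.83	2.46	20.33	2013.98	0.999	P
BRCA2	c.7008-?_7805+?del	.	0.81	2786.04	18.12	.	.	50481.75	1.000	P
BRCA2	c.7008-1G>A	p.(=)	0.97	2.00	1.79	.	.	3.57	0.991	P
BRCA2	c.7008-2A>G	.	0.97	1.52	.	1.02	2.50	3.90	0.992	P
BRCA2	c.7617+2T>G	.	0.97	2.72	0.81	1.08	1.59	3.75	0.992	P
BRCA2	c.7618-2A>G	.	0.97	1.30	1.96	1.03	2.29	6.03	0.995	P
BRCA2	c.7806-2_7806-1dup	.	0.99	8.77	4.38	.	.	38.36	1.000	P
BRCA2	c.7806-2A>G	.	0.97	7.11	1.20	1.41	1.67	20.04	0.998	P
BRCA2	c.7975A>G	p.(Arg2659Gly)	0.81	1950.00	0.86	1.10	5.07	9380.28	1.000	P
BRCA2	c.7976+1G>A	.	0.97	0.71	.	1.22	160.57	138.22	1.000	P
BRCA2	c.7977-1G>C	.	0.97	1984739.68	10.20	.	.	20246907.80	1.000	P
BRCA2	c.8023A>G	p.(Ile2675Val)	0.64	605.14	0.88	1.05	2.88	1612.05	1.000	P
BRCA2	c.8488-1G>A	.	0.97	.	.	1.13	3.73	4.21	0.993	P
BRCA2	c.8632+1G>A	.	0.97	21.93	0.74	.	.	16.19	0.998	P
BRCA2	c.8633-24_8634del	.	0.97	.	.	1.05	3.16	3.32	0.991	P
BRCA2	c.8633-2A>G	.	0.97	1.29	1.06	1.05	6.65	9.58	0.997	P
BRCA2	c.8755-1G>A	.	0.97	9.40	2.85	1.31	8.13	284.48	1.000	P
BRCA2	c.8954-1_8955delinsAA	.	0.97	.	.	1.28	3.77	4.81	0.994	P
BRCA2	c.9118-2A>G	.	0.97	10.89	0.51	.	.	5.56	0.994	P
BRCA2	c.9257-?_(*1_?)del	.	0.81	31.48	3.10	.	.	97.53	0.998	P
BRCA2	c.9371A>T	p.(Asn3124Ile)	0.81	402919.02	0.54	2.07	81.64	36698863.68	1.000	P
BRCA1	c.181T>A	p.(Cys61Ser)	0.81	1.39	3.73	.	.	5.19	0.957	LP
BRCA1	c.1A>G	p.(Met1?)	0.96	1.27	2.23	.	.	2.83	0.985	LP
BRCA1	c.230_238del	p.(Thr77_Phe79del)	0.66	1.83	16.45	.	.	30.16	0.983	LP
BRCA1	c.4185_4185+3del	.	0.97	2.09	.	1.048	.	2.19032	0.986	LP
BRCA1	c.4185+1G>T	.	0.97	.	.	1.10	2.64	2.91	0.989	LP
BRCA1	c.4479_4484+2dup	.	0.97	0.96	3.16	.	.	3.04	0.990	LP
BRCA1	c.4676-2A>G	.	0.97	.	.	1.03	2.29	2.36	0.987	LP
BRCA1	c.5193+1G>A	.	0.97	1.27	1.67	.	.	2.12	0.986	LP
BRCA1	c.5207T>G	p.(Val1736Gly)	0.81	.	.	1.10	6.53	7.20	0.968	LP
BRCA1	c.5213G>A	p.(Gly1738Glu)	0.81	1.18	.	1.18	8.89	12.30	0.981	LP
BRCA1	c.5216A>T	p.(Asp1739Val)	0.81	0.82	.	1.03	7.93	6.72	0.966	LP
BRCA1	c.5243G>A	p.(Gly1748Asp)	0.81	3.80	3.16	1.03	0.92	11.47	0.980	LP
BRCA1	c.5333-6T>G	.	0.97	0.68	3.73	.	.	2.55	0.988	LP
BRCA1	c.5558A>G	p.(Tyr1853Cys)	0.81	12.66	0.40	1.07	2.29	12.39	0.981	LP
BRCA1	c.80+5G>A	.	0.34	15.05	1.49	1.03	2.60	60.32	0.969	LP
BRCA2	c.476-1G>A	.	0.97	1.23	.	1.02	2.18	2.75	0.989	LP
BRCA2	c.67+2T>C	.	0.97	.	.	1.13	1.86	2.10	0.985	LP
BRCA2	c.681+1G>A	.	0.97	1.94	1.08	.	.	2.10	0.985	LP
BRCA2	c.7007+5G>C	.	0.34	8.55	0.95	1.08	4.75	41.64	0.955	LP
BRCA2	c.7819A>C	p.(Thr2607Pro)	0.66	.	.	1.02	11.62	11.90	0.959	LP
BRCA2	c.8009C>T	p.(Ser2670Leu)	0.29	17.87	4.74	1.37	1.22	141.76	0.983	LP
BRCA2	c.8035G>T	p.(Asp2679Tyr)	0.81	3.54	1.06	1.02	1.24	4.76	0.953	LP
BRCA2	c.8331+1G>A	.	0.97	.	.	1.02	2.72	2.79	0.989	LP
BRCA2	c.8331+1G>T	.	0.97	1.17	1.77	.	.	2.07	0.985	LP
BRCA2	c.8754+4A>G	.	0.34	4.87	3.13	1.34	2.22	45.36	0.959	LP
BRCA2	c.8975_9100del	p.(Pro2992_Thr3033del)	0.81	.	.	1.24	13.48	16.78	0.986	LP
BRCA2	c.9257-1G>C	.	0.34	1.29	0.76	1.16	47.50	54.24	0.965	LP
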