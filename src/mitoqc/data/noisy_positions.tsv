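position	rcrs_base	sample	varfreq_mean	varfreq_sd	second_variant	numt
309	C	9947A	37.76	23.81	DEL	1
309	C	2800M	36.18	5.69	DEL	1
315	C	9947A	77.40	10.21	INS	0
315	C	2800M	81.84	4.08	INS	0
438	C	9947A	86.36	6.83	DEL	0
438	C	2800M	87.33	4.34	DEL	0
498	C	9947A	84.75	2.13	DEL	0
498	C	2800M	82.32	2.74	DEL	0
937	T	9947A	88.09	6.60	DEL	0
937	T	2800M	86.77	3.67	DEL	0
1296	A	9947A	85.84	6.01	DEL	1
1296	A	2800M	81.91	5.73	DEL	1
2135	A	9947A	83.75	4.54	DEL	0
2135	A	2800M	83.21	5.95	DEL	0
5287	A	9947A	85.76	6.11	DEL	1
5287	A	2800M	86.34	1.48	DEL	1
5752	A	9947A	75.32	14.18	DEL	1
5752	A	2800M	73.43	9.89	DEL	1
7402	C	9947A	74.03	6.31	DEL	0
7402	C	2800M	77.93	9.17	DEL	0
7513	T	9947A	72.39	13.67	DEL	0
7513	T	2800M	72.28	9.02	DEL	0
8249	G	9947A	56.47	14.13	INS	0
8249	G	2800M	61.26	4.32	INS	0
8252	C	9947A	84.66	4.62	G	0
8252	C	2800M	84.34	5.54	G	0
8254	C	9947A	60.31	5.32	DEL	0
8254	C	2800M	57.51	5.16	DEL	0
8255	G	9947A	75.14	11.57	DEL	1
8255	G	2800M	79.94	4.71	DEL	1
8256	T	9947A	62.78	10.49	DEL	0
8256	T	2800M	58.67	5.08	DEL	0
8962	A	9947A	83.35	5.73	DEL	0
8962	A	2800M	83.22	5.42	DEL	0
9100	A	9947A	78.83	4.36	G	0
9100	A	2800M	81.09	3.85	G	0
10151	A	9947A	87.12	5.91	DEL	0
10151	A	2800M	85.59	4.16	DEL	0
11038	A	9947A	87.17	5.73	DEL	0
11038	A	2800M	87.41	3.10	DEL	0
12425	A	9947A	66.95	12.42	DEL	0
12425	A	2800M	76.17	4.26	DEL	0
13237	A	9947A	88.15	4.95	DEL	1
13237	A	2800M	89.89	2.88	DEL	1
13758	C	9947A	54.32	6.28	DEL	0
13758	C	2800M	58.76	4.84	DEL	0
14510	A	9947A	83.97	7.57	DEL	0
14510	A	2800M	84.23	5.51	DEL	0
14754	C	9947A	81.30	12.77	DEL	1
14754	C	2800M	79.64	5.44	DEL	1
14774	C	9947A	87.38	10.76	DEL	1
14774	C	2800M	86.89	3.94	DEL	1
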