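chrom	size_mb	n_snps	cm_avg	cm_female	cm_male
1	99.26	3530	108.97	97.51	121.82
1A	68.01	2326	84.75	77.69	92.94
2	143.7	4897	112.22	97.25	128.89
3	111.67	3476	93.56	93.93	94.47
4	70.22	2453	96.24	92.13	102.26
4A	20.1	684	60.96	50.89	71.9
5	61.39	1986	95.94	83.84	109.18
6	34.87	1257	71.6	60.69	83.42
7	38.89	1259	82.3	77.56	88.06
8	26.64	950	52.11	45.28	59.65
9	25.15	895	72.8	70.95	75.52
10	20.9	1082	61.41	54.16	69.63
11	21.17	1125	56.09	47.28	65.69
12	21.11	1089	58.54	44.7	73.05
13	18.28	918	54.88	53.96	56.51
14	16.57	846	50.57	40.76	61.04
15	14.26	727	50.35	48.9	52.49
17	10.98	569	42.38	44.95	40.29
18	11.36	525	46.82	44.54	49.69
19	11.02	527	42.91	42.35	44.13
20	15.23	788	57.24	62.55	52.64
21	7.69	334	44.62	43.53	46.2
22	4.68	196	47.57	48.03	47.85
23	6.87	322	54.25	51.9	57.41
24	6.77	400	48.61	43.16	54.72
26	6.07	276	43.97	42.99	45.46
27	5.64	215	51.21	60.95	42.34
28	5.29	238	56.81	58.11	56.64
Z	73.43	2414			106.04
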