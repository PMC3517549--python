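gene	position	protein_length	connectivity	enc	percent_used_codons	dn	ds	omega
TLR1	1	786	9	53.65	80.14	1.45	6.76	0.22
TLR2	1	784	18	53.95	94.69	1.42	5.99	0.24
TLR3	1	904	6	54.08	95.18	1.04	6.42	0.16
TLR4	1	839	22	53.78	81.23	2.08	7.29	0.29
TLR5	1	858	5	54.41	86.89	1.47	7.22	0.20
TLR6	1	796	3	52.10	95.24	0.78	3.18	0.24
TLR7	1	1049	1	53.27	98.21	0.60	3.75	0.16
TLR8	1	1041	2	56.75	93.64	1.12	4.83	0.23
TLR9	1	1032	0	42.94	90.91	1.32	9.29	0.14
MyD88	2	317	24	47.24	70.20	0.74	7.48	0.10
TIRAP	2	221	14	45.99	44.77	1.49	9.03	0.17
TRAM	2	235	0	54.23	97.45	0.24	1.03	0.23
TRIF	2	712	20	47.77	63.45	1.70	10.03	0.17
TOLLIP	2	274	18	43.77	59.17	0.34	6.41	0.05
IRAK1	3	682	35	45.46	17.68	1.98	8.55	0.23
IRAK4	3	460	7	49.63	59.62	1.04	8.46	0.12
TRAF6	4	522	303	55.21	91.28	0.63	8.45	0.07
TRAF3	4	568	41	50.62	89.55	0.50	14.01	0.04
TAB1	5	504	13	47.06	52.35	0.40	8.76	0.05
TAB2	5	693	13	52.61	93.13	0.18	2.14	0.09
TAK1	5	579	0	55.87	30.50	0.04	4.91	0.01
RIPK1	4	671	0	52.79	62.46	1.36	6.87	0.20
IKKa	6	745	7	52.84	90.62	0.42	7.30	0.06
IKKb	6	754	52	48.56	49.07	0.70	7.80	0.09
IKKg	6	487	46	46.90	52.58	0.78	13.40	0.06
IKKz	6	631	271	44.71	37.77	0.58	7.87	0.07
TBK1	6	729	17	50.34	99.18	0.40	8.95	0.04
MEK1	6	393	33	51.21	98.99	0.12	7.85	0.02
MEK2	6	400	17	43.04	71.32	0.13	4.04	0.03
MKK3	6	318	12	41.53	74.35	0.05	4.89	0.01
MKK6	6	334	15	52.56	91.76	0.13	5.37	0.02
MKK4	6	399	24	53.89	80.36	0.11	3.06	0.03
MKK7	6	419	17	45.58	67.25	0.24	6.11	0.04
IKBa	7	317	62	49.01	92.64	0.77	12.87	0.06
MAPK1	7	360	176	54.63	93.77	0.03	10.73	0.00
MAPK3	7	357	113	42.97	77.21	0.17	2.69	0.06
MAPK11	7	364	15	46.54	95.60	0.25	10.57	0.02
MAPK12	7	367	18	44.31	64.72	0.43	8.22	0.05
MAPK13	7	365	9	44.18	88.30	0.50	7.92	0.06
MAPK14	7	360	81	52.03	99.72	0.17	6.29	0.03
MAPK8	7	384	68	54.79	89.23	0.14	5.10	0.03
MAPK9	7	424	38	54.63	69.18	0.10	13.22	0.01
MAPK10	7	422	15	53.75	79.50	0.04	4.09	0.01
p105	8	968	72	54.17	78.79	0.37	3.73	0.10
p65	8	548	109	45.88	69.69	0.80	15.55	0.05
IRF5	8	498	6	43.72	69.37	0.48	9.77	0.05
IRF7	8	503	12	43.59	55.52	1.70	12.26	0.14
IRF3	8	452	16	48.15	43.31	1.43	6.04	0.24
FOS	8	380	52	44.18	83.29	0.57	11.50	0.05
JUN	8	331	111	42.17	82.39	0.21	7.80	0.03
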