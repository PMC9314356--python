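stage	study	d1_n_high_risk	d1_n_controls	d1_pct_controls_retained	d1_n_risk_matched	d1_n_cases	d1_pct_cases_retained	d2_n_high_risk	d2_n_controls	d2_pct_controls_retained	d2_n_risk_matched	d2_n_cases	d2_pct_cases_retained
discovery	ADC1	52	512	10.2	842	1524	55.2	30	150	20.0	773	1021	75.7
discovery	ADC2	16	155	10.3	386	620	62.3	9	41	22.0	212	353	60.1
discovery	ADC3	57	566	10.1	379	666	56.9	27	132	20.5	357	391	91.3
discovery	ADC4	38	376	10.1	222	304	73.0	20	100	20.0	115	160	71.9
discovery	ADC5	51	503	10.1	187	285	65.6	24	119	20.2	147	178	82.6
discovery	ADC6	34	337	10.1	68	213	31.9	19	93	20.4	94	121	77.7
discovery	MAYO	112	1117	10.0	626	754	83.0	63	313	20.1	436	492	88.6
discovery	UM/VU/MSSM	113	1108	10.2	753	1123	67.1	51	251	20.3	430	661	65.1
discovery	ACT+GenDiff	157	1556	10.1	425	524	81.1	63	314	20.1	198	234	84.6
discovery	MIRAGE	51	509	10.0	101	137	73.7	38	190	20.0	68	78	87.2
discovery	WASHU1	18	176	10.2	137	253	54.2	10	48	20.8	65	141	46.1
discovery	ROSMAP	72	717	10.0	192	237	81.0	23	114	20.2	18	87	20.7
discovery	UPITT	82	811	10.1	794	1152	68.9	32	158	20.3	545	664	82.1
discovery	OHSU	18	180	10.0	119	174	68.4	5	25	20.0	49	73	67.1
discovery	TGEN2	36	360	10.0	364	613	59.4	16	76	21.1	251	396	63.4
discovery	NIA-LOAD	102	1007	10.1	582	760	76.6	58	289	20.1	463	571	81.1
discovery	ROSMAP2	22	214	10.3	50	59	84.7	3	15	20.0	0	18	0.0
discovery	WASHU2	8	71	11.3	29	36	80.6	4	16	25.0	16	19	84.2
discovery	MTC	19	188	10.1	220	252	87.3	5	22	22.7	48	143	33.6
discovery	TARCC	18	176	10.2	241	306	78.8	10	47	21.3	122	184	66.3
discovery	WHICAP	56	553	10.1	17	72	23.6	23	113	20.4	8	16	50.0
discovery	ADNI-1	13	127	10.2	174	350	49.7	6	28	21.4	97	230	42.2
discovery	CHS	168	1661	10.1	274	451	60.8	66	330	20.0	99	148	66.9
discovery	FHS	191	1901	10.0	137	288	47.6	74	370	20.0	54	94	57.4
discovery	EADI	620	6172	10.0	1636	2167	75.5	247	1235	20.0	870	1072	81.2
discovery	GERAD	139	1388	10.0	2354	2992	78.7	62	310	20.0	1006	1623	62.0
replication	AddNeuroMed	19	183	10.4	38	223	17.0	9	44	20.5	19	121	15.7
replication	ADC7	79	784	10.1	45	513	8.8	51	252	20.2	57	320	17.8
replication	ADNI-GO/2/3	38	374	10.2	37	211	17.5	23	113	20.4	38	142	26.8
replication	DemGene	75	741	10.1	163	1085	15.0	34	168	20.2	130	671	19.4
replication	GENDER/SATSA/HARMONY	77	764	10.1	39	306	12.7	40	196	20.4	34	148	23.0
replication	TwinGene	608	6080	10.0	30	287	10.5	353	1765	20.0	31	156	19.9
replication	AIBL	77	762	10.1	13	111	11.7	36	180	20.0	12	71	16.9
replication	SydneyMAS	83	830	10.0	16	95	16.8	37	182	20.3	10	31	32.3
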