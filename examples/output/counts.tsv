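sample	OTU1	OTU2	OTU3	OTU4	OTU5	OTU6	OTU7	OTU8	OTU9	OTU10	OTU11	OTU12	OTU13	OTU14	OTU15	OTU16	OTU17	OTU18	OTU19	OTU20	OTU21	OTU22	OTU23	OTU24	OTU25	OTU26	OTU27	OTU28	OTU29	OTU30
S1	1	2	4	243	23	6	68	12	8	3	25	14	116	4	47	360	56	1	14	384	2	23	11	11	10	54	103	22	15	8
S2	4	0	1	131	37	1	60	34	21	6	30	20	108	2	32	183	28	1	18	414	13	50	26	6	8	60	93	16	15	10
S3	5	13	0	112	29	1	1264	81	60	1	6	25	26	1	224	1	3	1	8	50	1	16	363	13	13	10	45	3	17	44
S4	9	18	4	511	24	8	2952	240	214	0	7	99	60	9	742	11	15	3	66	239	2	58	964	30	26	16	90	9	40	50
S5	7	7	6	61	31	17	141	11	76	16	22	8	4	4	95	5	3	5	26	927	1	195	1472	18	23	108	75	37	26	3
S6	3	1	10	32	16	2	89	8	60	9	3	1	4	1	31	5	4	5	5	111	0	103	627	9	12	47	48	22	8	3
S7	6	7	19	1173	233	55	276	81	532	27	102	26	24	14	492	52	39	160	79	3375	30	133	2287	82	93	396	852	146	139	48
S8	4	0	1	180	21	9	42	52	85	6	6	1	4	1	58	3	7	22	8	483	13	36	746	8	16	92	94	32	16	11
S9	3	0	3	41	17	11	22	21	20	9	20	21	1	5	31	33	11	83	54	91	39	296	126	6	24	14	62	2	15	17
S10	6	0	7	136	73	31	75	42	45	34	50	58	4	9	109	186	82	318	139	501	237	580	603	53	56	49	186	28	84	78
S11	5	1	2	492	169	20	10	36	56	3	8	8	18	10	157	284	105	5	104	659	133	145	169	51	38	368	348	153	173	4
S12	0	0	1	176	28	11	5	4	21	0	8	2	3	1	78	149	34	1	18	584	28	39	84	19	16	98	67	61	11	4
S13	5	1	0	149	21	7	1468	240	26	10	14	141	18	2	2	59	15	116	10	6	6	49	47	8	12	1	120	1	29	350
S14	5	1	10	259	38	6	1804	189	20	11	2	236	33	2	5	57	29	137	8	22	6	30	64	23	14	5	122	1	51	319
S15	18	0	104	429	72	14	6	12	270	133	10	11	69	12	25	1221	11	18	78	1883	130	93	34	32	65	608	298	248	45	9
S16	2	0	39	190	34	8	1	2	146	66	63	4	20	5	11	1053	7	8	15	1610	79	84	8	14	30	273	106	116	31	4
S17	4	1	3	193	4	17	1	4	27	2	6	4	4	3	56	67	31	2	14	1399	106	43	37	10	18	146	174	57	9	9
S18	6	0	1	218	7	7	4	10	47	2	38	9	4	6	127	191	25	8	31	927	98	64	88	21	20	219	161	85	10	11
S19	17	0	100	82	41	17	383	1392	69	222	20	1167	3	10	26	487	203	8889	90	32	253	893	181	35	41	4	359	3	57	557
S20	5	0	14	27	1	2	98	477	21	84	7	341	2	2	5	74	19	2584	12	16	118	196	42	4	7	4	56	0	10	223
S21	11	1	19	136	15	19	108	80	38	16	13	103	1	10	40	19	32	390	61	92	17	82	405	13	23	21	64	10	21	66
S22	9	0	17	137	9	8	77	92	21	6	4	79	1	0	10	18	21	229	9	63	28	30	307	16	13	11	129	3	26	37
S23	20	1	69	713	41	23	30	157	118	47	48	49	135	21	95	1421	106	12	19	1214	331	275	36	41	75	411	345	143	31	34
S24	13	0	43	687	91	16	22	74	116	46	41	79	108	13	52	1158	45	13	95	1382	381	172	21	32	50	374	632	106	74	42
S25	9	0	98	588	38	15	8	31	156	85	26	16	34	16	45	2031	24	21	27	3076	123	156	30	39	47	462	236	152	61	13
S26	5	0	78	204	45	13	1	13	169	64	14	10	24	10	21	139	7	16	30	1433	113	123	9	14	19	283	91	69	39	1
S27	11	0	1279	63	13	9	21	10	279	1993	41	8	6	8	7	37	13	1499	21	3555	50	387	463	32	37	474	271	154	19	14
S28	0	0	292	25	9	3	1	7	62	428	4	2	3	0	1	4	14	270	9	235	12	119	151	3	13	135	33	27	4	7
S29	7	1	11	64	95	14	480	76	25	54	59	17	5	8	16	7	36	237	34	707	3	511	8903	46	29	121	164	39	8	21
S30	5	6	5	37	19	18	227	29	12	29	2	9	2	3	8	1	8	83	23	360	1	276	3279	15	11	50	154	14	20	8
S31	3	1	34	20	9	5	810	18	17	88	17	104	0	2	1	0	14	7520	17	29	2	134	2880	15	12	2	84	2	15	53
S32	4	2	56	40	30	9	1375	128	28	124	19	129	3	6	11	0	21	9955	22	11	4	169	3525	5	24	7	129	2	29	113
S33	9	0	1	256	48	7	8	80	13	3	10	42	171	7	107	16150	38	2	22	148	201	35	0	14	23	15	121	9	7	80
S34	16	0	2	749	88	16	13	174	47	2	55	67	275	12	172	21502	72	1	37	254	811	43	0	32	29	29	269	22	46	100
S35	5	1	1	66	170	19	3	4	32	0	36	4	4	8	564	54	74	5	45	8944	167	433	1379	31	29	1034	205	473	57	3
S36	14	0	1	56	26	14	2	5	32	4	8	2	0	13	455	17	25	3	44	5282	93	396	947	26	35	761	106	414	33	3
S37	8	1	11	46	10	17	14	3	15	99	7	2	1	1	5	16	44	26	15	1178	8	303	759	10	23	274	134	110	8	4
S38	7	1	63	70	121	27	18	5	45	164	4	2	5	4	2	8	89	72	26	4829	12	439	1493	35	45	613	297	254	41	4
S39	8	1	9	284	21	20	269	41	45	5	30	57	8	3	25	16	32	69	38	331	5	50	630	20	35	41	137	15	21	35
S40	7	0	20	534	56	15	443	169	165	17	27	78	11	6	27	25	64	140	50	468	13	135	1232	36	59	81	192	38	67	60
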