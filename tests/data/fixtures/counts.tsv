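# sipscreen output
# bundle: sipscreen-fixture-v1
# seed: 20230211
taxon	C13_E_coli_1d:1	C13_E_coli_1d:2	C13_E_coli_1d:3	C13_E_coli_1d:4	C13_E_coli_1d:5	C13_E_coli_1d:6	C13_E_coli_1d:7	C13_E_coli_1d:8	C13_E_coli_1d:9	C13_E_coli_1d:10	C13_E_coli_1d:11	C13_E_coli_1d:12	C13_E_coli_1d:13	C12_E_coli_1d:1	C12_E_coli_1d:2	C12_E_coli_1d:3	C12_E_coli_1d:4	C12_E_coli_1d:5	C12_E_coli_1d:6	C12_E_coli_1d:7	C12_E_coli_1d:8	C12_E_coli_1d:9	C12_E_coli_1d:10	C12_E_coli_1d:11	C12_E_coli_1d:12	C12_E_coli_1d:13	C13_E_coli_2d:1	C13_E_coli_2d:2	C13_E_coli_2d:3	C13_E_coli_2d:4	C13_E_coli_2d:5	C13_E_coli_2d:6	C13_E_coli_2d:7	C13_E_coli_2d:8	C13_E_coli_2d:9	C13_E_coli_2d:10	C13_E_coli_2d:11	C13_E_coli_2d:12	C13_E_coli_2d:13	C12_E_coli_2d:1	C12_E_coli_2d:2	C12_E_coli_2d:3	C12_E_coli_2d:4	C12_E_coli_2d:5	C12_E_coli_2d:6	C12_E_coli_2d:7	C12_E_coli_2d:8	C12_E_coli_2d:9	C12_E_coli_2d:10	C12_E_coli_2d:11	C12_E_coli_2d:12	C12_E_coli_2d:13
prey_E_coli	0	0	0	0	0	6	692	893	1003	978	950	930	975	40	61	45	44	57	44	54	51	56	42	41	48	57	0	0	0	0	0	2	717	959	943	1002	995	969	985	56	44	45	41	52	39	59	46	51	39	38	46	45
t0000	8	4	4	7	4	23	1865	2786	2703	2698	2765	2697	2655	123	133	123	145	139	178	159	140	139	139	166	165	140	6	10	4	10	10	34	1951	2669	2712	2666	2662	2691	2635	151	148	143	130	135	155	142	119	120	133	157	165	137
t0001	30	50	38	32	38	48	945	1300	1267	1295	1264	1350	1341	99	122	107	104	101	105	100	98	106	93	95	111	88	42	39	44	49	44	52	893	1337	1323	1309	1319	1322	1355	89	95	104	95	98	96	100	137	116	92	113	114	115
t0002	6	8	8	14	3	8	22	15	27	29	21	23	29	11	3	12	6	3	11	7	7	9	6	7	4	14	12	6	3	5	6	5	23	30	22	23	24	18	25	7	6	9	10	8	1	9	5	6	7	5	4	12
t0003	101	92	96	100	90	80	26	0	0	0	0	0	0	90	85	78	74	84	82	82	76	89	91	92	84	82	104	93	88	96	96	85	33	0	0	0	0	0	0	87	82	78	86	109	78	83	76	85	73	81	64	78
t0004	115	125	114	98	132	129	34	0	0	0	0	0	0	111	119	134	109	109	110	117	125	144	112	113	102	121	121	151	136	120	119	120	35	0	0	0	0	0	0	107	119	99	118	102	119	118	101	122	101	111	124	101
t0005	1404	1471	1389	1458	1342	1456	431	2	0	0	0	0	0	1328	1327	1359	1356	1309	1305	1359	1373	1317	1327	1311	1336	1374	1399	1372	1376	1336	1412	1464	385	3	0	0	0	0	0	1373	1396	1347	1292	1310	1344	1410	1386	1381	1393	1325	1297	1361
t0006	3	5	6	1	8	3	3	0	0	0	0	0	0	7	0	5	7	4	3	4	6	5	1	5	1	4	5	4	6	8	14	6	2	0	0	0	0	0	0	2	7	9	5	3	5	2	2	5	5	3	6	5
t0007	41	23	31	29	29	36	4	0	0	0	0	0	0	26	30	30	28	19	26	30	20	37	35	13	41	24	34	34	38	31	11	21	4	0	0	0	0	0	0	30	23	27	33	29	30	19	30	23	35	27	27	23
t0008	11	9	3	6	6	3	1	0	0	0	0	0	0	6	8	8	5	7	4	9	7	10	14	5	7	11	4	3	6	5	5	10	1	0	0	0	0	0	0	7	3	13	10	7	5	10	3	8	6	8	7	13
t0009	1004	1007	1035	1069	1042	1018	312	1	0	0	0	0	0	1024	925	1024	914	1025	969	1014	1006	980	1005	1004	963	949	1039	1029	1044	1054	1053	1042	311	1	0	0	0	0	0	978	959	989	966	1014	984	944	1027	985	999	959	940	987
t0010	9	5	4	4	7	9	1	0	0	0	0	0	0	2	6	9	7	4	3	2	4	6	6	6	2	4	5	5	8	9	8	11	4	0	0	0	0	0	0	3	2	5	8	2	6	2	2	3	4	3	5	10
t0011	0	1	1	1	1	2	0	0	0	0	0	0	0	1	0	3	1	2	2	0	3	0	2	0	1	1	0	0	0	2	2	1	0	0	0	0	0	0	0	2	3	0	0	1	1	2	0	0	1	3	3	2
t0012	100	94	96	90	83	90	22	0	0	0	0	0	0	85	74	95	81	93	89	101	87	92	101	83	113	102	113	98	101	89	98	92	36	0	0	0	0	0	0	86	82	113	106	82	88	90	96	102	102	98	91	104
t0013	143	140	172	125	170	135	44	0	0	0	0	0	0	147	144	152	147	159	130	141	151	125	134	158	163	134	152	126	148	142	141	144	50	0	0	0	0	0	0	150	129	141	158	155	160	137	119	157	150	133	130	129
t0014	407	396	392	402	392	394	123	1	0	0	0	0	0	368	399	345	387	396	374	377	368	388	383	394	394	401	368	428	392	421	427	341	114	0	0	0	0	0	0	388	377	357	351	405	376	357	360	394	386	371	405	388
t0015	327	373	364	348	349	332	103	0	0	0	0	0	0	300	347	314	344	329	344	306	303	319	306	312	325	354	354	323	358	342	341	337	96	0	0	0	0	0	0	325	324	330	319	300	306	336	342	295	311	345	330	347
t0016	89	95	115	95	110	78	22	0	0	0	0	0	0	101	97	113	83	108	106	100	90	106	98	98	99	94	99	97	100	117	84	96	30	0	0	0	0	0	0	104	87	88	107	88	105	90	98	92	102	94	93	85
t0017	164	171	153	139	165	184	46	1	0	0	0	0	0	150	163	138	175	142	152	153	149	141	162	140	153	132	132	169	165	153	149	169	27	0	0	0	0	0	0	156	140	179	173	146	160	152	151	134	144	157	155	165
t0018	253	224	234	241	261	255	75	0	0	0	0	0	0	253	257	233	258	231	228	231	234	240	211	227	233	225	264	238	222	283	255	237	67	0	0	0	0	0	0	219	239	231	249	229	220	231	198	223	229	277	245	240
t0019	20	26	22	20	26	15	4	0	0	0	0	0	0	23	21	18	20	9	11	22	16	23	17	14	17	20	28	20	19	19	18	15	6	0	0	0	0	0	0	19	19	7	24	15	21	21	12	22	20	14	13	24
t0020	62	62	61	67	59	65	21	0	0	0	0	0	0	57	58	48	43	50	54	50	51	54	63	52	45	56	53	65	57	60	47	71	11	0	0	0	0	0	0	42	57	52	48	51	38	64	50	56	55	60	48	41
t0021	4	12	4	6	12	5	1	0	0	0	0	0	0	2	5	3	3	8	8	2	3	6	4	6	4	1	3	6	2	6	7	3	1	0	0	0	0	0	0	12	3	6	11	2	3	3	1	7	5	5	5	6
t0022	305	281	309	286	287	284	92	0	0	0	0	0	0	298	275	275	277	281	273	272	257	267	293	293	277	302	291	317	296	292	281	296	89	0	0	0	0	0	0	272	294	264	310	298	296	276	288	262	269	292	295	275
t0023	10	14	18	13	12	20	4	0	0	0	0	0	0	9	12	18	8	13	22	13	16	22	14	9	10	17	18	12	11	8	13	18	5	0	0	0	0	0	0	10	13	12	15	5	21	13	17	8	10	7	18	15
t0024	0	1	1	0	1	0	0	0	0	0	0	0	0	2	1	0	0	1	1	0	0	1	1	0	0	1	2	0	0	1	0	1	0	0	0	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0	0
t0025	11	7	11	6	14	12	1	0	0	0	0	0	0	11	15	20	18	15	16	11	17	14	8	12	15	8	9	13	15	14	12	14	6	0	0	0	0	0	0	14	16	17	8	13	16	10	9	14	14	11	11	11
t0026	213	178	193	203	213	178	58	0	0	0	0	0	0	195	182	179	200	165	212	168	209	174	209	197	155	173	192	199	217	204	214	200	57	0	0	0	0	0	0	174	189	198	197	198	188	188	206	198	180	163	215	168
t0027	6	4	3	2	3	1	1	0	0	0	0	0	0	1	0	3	2	5	4	2	4	1	3	2	6	3	8	1	3	1	0	4	2	0	0	0	0	0	0	3	4	0	1	6	1	1	4	3	4	4	3	3
t0028	48	37	42	43	37	35	10	1	0	0	0	0	0	32	56	34	45	49	42	32	47	39	38	53	38	35	45	45	51	41	40	32	10	0	0	0	0	0	0	47	39	39	41	52	40	34	36	42	35	43	37	33
t0029	106	85	81	95	104	96	37	0	0	0	0	0	0	98	75	75	109	83	92	82	82	90	82	92	88	73	98	97	90	82	93	77	34	1	0	0	0	0	0	86	101	98	88	85	98	96	79	86	96	93	104	77
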