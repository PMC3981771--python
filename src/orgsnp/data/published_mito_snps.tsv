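cultivar	position	ref	alt	quality	read_depth	depth_reference	depth_alternate	location	unique	polymorphic
SUK-A	117620	G	A	78	21	0	20	IGS	0	0
DEK	117620	G	A	61	13	0	11	IGS	0	0
AJW	117620	G	A	69	14	0	13	IGS	0	0
PER	117620	G	A	72	14	0	13	IGS	0	0
SUK-Q	117620	G	A	65	10	0	10	IGS	0	0
RAB	117620	G	A	81	16	0	14	IGS	0	0
SHA	117620	G	A	81	21	0	21	IGS	0	0
MOS-A	117620	G	A	73	12	0	10	IGS	0	0
MOS-H	117620	G	A	62	13	0	11	IGS	0	0
SHA	130703	C	T	34	20	9	7	IGS	1	1
SHA	130707	C	T	36	24	14	7	IGS	1	1
SHA	130715	G	A	95	32	22	8	IGS	1	1
SUK-A	157036	C	T	123	57	0	54	IGS	0	0
DEK	157036	C	T	123	45	0	42	IGS	0	0
AJW	157036	C	T	106	53	0	52	IGS	0	0
PER	157036	C	T,G	100	37	0	35	IGS	0	0
SUK-Q	157036	C	T	76	10	0	9	IGS	0	0
RAB	157036	C	T	91	21	0	20	IGS	0	0
SHA	157036	C	T	100	30	0	28	IGS	0	0
MOS-A	157036	C	T	86	28	0	24	IGS	0	0
MOS-H	157036	C	T	101	32	0	28	IGS	0	0
SUK-A	215792	A	C	222	265	0	250	IGS	0	0
DEK	215792	A	C	222	196	0	181	IGS	0	0
AJW	215792	A	C	222	178	0	165	IGS	0	0
PER	215792	A	C	222	160	1	153	IGS	0	1
SUK-Q	215792	A	C	206	84	0	75	IGS	0	0
RAB	215792	A	C	218	123	0	113	IGS	0	0
SHA	215792	A	C	222	118	0	109	IGS	0	0
MOS-A	215792	A	C	222	132	0	127	IGS	0	0
MOS-H	215792	A	C	222	142	0	131	IGS	0	0
SUK-Q	260494	A	T	18	115	97	15	IGS	1	1
MOS-H	329782	G	A	60	21	16	5	IGS	1	1
SUK-A	349157	A	T	75	16	0	16	IGS	0	0
DEK	349157	A	T	70	15	0	15	IGS	0	0
PER	349157	A	T	73	15	0	14	IGS	0	0
MOS-A	350750	C	A	222	125	0	121	IGS	1	0
MOS-H	452157	C	G	38	159	129	22	IGS	1	1
SUK-A	457989	C	A	66	12	0	12	IGS	0	0
AJW	457989	C	A	64	23	0	23	IGS	0	0
PER	457989	C	A	79	18	0	16	IGS	0	0
SUK-Q	457989	C	A	66	10	0	10	IGS	0	0
RAB	457989	C	A	52	11	0	11	IGS	0	0
SHA	457989	C	A	63	19	0	19	IGS	0	0
MOS-A	457989	C	A	68	17	0	17	IGS	0	0
MOS-H	457989	C	A	75	17	0	17	IGS	0	0
SUK-A	457994	A	T	46	12	0	12	IGS	0	0
DEK	457994	A	T	42	10	0	10	IGS	0	0
AJW	457994	A	T	52	29	0	29	IGS	0	0
PER	457994	A	T	63	20	0	19	IGS	0	0
SUK-Q	457994	A	T	55	11	0	11	IGS	0	0
RAB	457994	A	T	48	14	0	14	IGS	0	0
SHA	457994	A	T	66	22	0	21	IGS	0	0
MOS-A	457994	A	T	49	18	0	18	IGS	0	0
MOS-H	457994	A	T	62	22	0	21	IGS	0	0
SUK-A	458029	A	C	62	15	0	13	IGS	0	0
DEK	458029	A	C	64	11	0	10	IGS	0	0
AJW	458029	A	C	71	30	0	30	IGS	0	0
PER	458029	A	C	63	20	0	20	IGS	0	0
SUK-Q	458029	A	C	60	17	0	17	IGS	0	0
RAB	458029	A	C	45	16	0	16	IGS	0	0
SHA	458029	A	C	63	20	0	20	IGS	0	0
MOS-A	458029	A	C	67	19	0	18	IGS	0	0
MOS-H	458029	A	C	54	21	0	21	IGS	0	0
SUK-A	458036	C	A	69	13	0	13	IGS	0	0
AJW	458036	C	A	72	30	0	29	IGS	0	0
PER	458036	C	A	79	20	0	18	IGS	0	0
SUK-Q	458036	C	A	70	17	0	16	IGS	0	0
RAB	458036	C	A	61	16	0	16	IGS	0	0
SHA	458036	C	A	60	20	0	20	IGS	0	0
MOS-A	458036	C	A	79	19	0	19	IGS	0	0
MOS-H	458036	C	A	78	21	0	21	IGS	0	0
SUK-A	464552	C	G	222	62	0	57	IGS	0	0
DEK	464552	C	G	222	52	0	52	IGS	0	0
AJW	464552	C	G	222	58	0	53	IGS	0	0
PER	464552	C	G	222	57	0	51	IGS	0	0
SUK-Q	464552	C	G	187	31	0	31	IGS	0	0
RAB	464552	C	G	222	37	0	34	IGS	0	0
SHA	464552	C	G	222	33	0	32	IGS	0	0
MOS-A	464552	C	G	222	38	0	35	IGS	0	0
MOS-H	464552	C	G	193	46	0	41	IGS	0	0
SUK-A	475318	A	T	173	110	0	105	IGS	0	0
DEK	475318	A	T	170	109	0	101	IGS	0	0
AJW	475318	A	T	189	107	0	101	IGS	0	0
PER	475318	A	T	163	93	0	88	IGS	0	0
SUK-Q	475318	A	T	129	28	0	26	IGS	0	0
RAB	475318	A	T	139	57	0	55	IGS	0	0
SHA	475318	A	T	152	62	0	58	IGS	0	0
MOS-A	475318	A	T	152	56	0	54	IGS	0	0
MOS-H	475318	A	T	119	59	0	56	IGS	0	0
SUK-A	475346	G	T	219	139	0	135	IGS	0	0
DEK	475346	G	T	220	104	0	102	IGS	0	0
AJW	475346	G	T	222	147	0	145	IGS	0	0
PER	475346	G	T	207	98	0	97	IGS	0	0
SUK-Q	475346	G	T	184	47	0	47	IGS	0	0
RAB	475346	G	T	196	67	0	66	IGS	0	0
SHA	475346	G	T	197	87	0	87	IGS	0	0
MOS-A	475346	G	T	206	75	0	73	IGS	0	0
MOS-H	475346	G	T	212	71	0	69	IGS	0	0
SHA	482322	A	C	93	11	0	11	IGS	1	0
SUK-A	503021	A	C	149	17	0	12	IGS	0	0
DEK	503021	A	C	122	11	0	11	IGS	0	0
MOS-A	559552	C	T	26	169	138	26	NS-matR	1	1
SUK-Q	571857	G	A	37	168	137	24	IGS	1	1
SHA	572726	G	A	22	194	152	31	IGS	1	1
SUK-A	587016	G	A	140	14	0	10	IGS	0	0
PER	587016	G	A	102	10	0	6	IGS	0	0
SUK-Q	590324	C	T	16	131	108	18	IGS	1	1
SUK-Q	590624	T	G	17	104	87	16	IGS	1	1
PER	629408	G	T	46	106	29	17	IGS	1	1
SUK-A	632571	A	C	88	105	0	96	IGS	0	0
DEK	632571	A	C	91	91	0	75	IGS	0	0
AJW	632571	A	C	76	89	0	79	IGS	0	0
PER	632571	A	C	78	65	0	60	IGS	0	0
SUK-Q	632571	A	C	68	45	0	39	IGS	0	0
RAB	632571	A	C	85	64	0	56	IGS	0	0
SHA	632571	A	C	67	51	0	48	IGS	0	0
MOS-A	632571	A	C	62	47	0	39	IGS	0	0
MOS-H	632571	A	C	75	70	0	64	IGS	0	0
SUK-A	642650	G	T	99	50	0	45	IGS	0	0
DEK	642650	G	T	149	47	0	36	IGS	0	0
AJW	642650	G	T	146	43	0	30	IGS	0	0
PER	642650	G	T	141	46	0	36	IGS	0	0
SUK-Q	642650	G	T	104	20	0	14	IGS	0	0
RAB	642650	G	T	136	24	0	21	IGS	0	0
SHA	642650	G	T	119	39	0	31	IGS	0	0
MOS-A	642650	G	T	128	41	0	34	IGS	0	0
MOS-H	642650	G	T	124	40	0	27	IGS	0	0
SUK-A	642669	T	G	210	51	0	50	IGS	0	0
DEK	642669	T	G	222	49	0	48	IGS	0	0
AJW	642669	T	G	222	43	0	42	IGS	0	0
PER	642669	T	G	222	46	0	45	IGS	0	0
SUK-Q	642669	T	G	222	20	0	20	IGS	0	0
RAB	642669	T	G	222	26	0	24	IGS	0	0
SHA	642669	T	G	222	41	0	37	IGS	0	0
MOS-A	642669	T	G	222	42	0	41	IGS	0	0
MOS-H	642669	T	G	222	41	0	40	IGS	0	0
SUK-A	642689	A	T	107	50	0	49	IGS	0	0
DEK	642689	A	T	137	46	0	45	IGS	0	0
AJW	642689	A	T	130	42	0	41	IGS	0	0
PER	642689	A	T	134	46	0	46	IGS	0	0
SUK-Q	642689	A	T	141	19	0	19	IGS	0	0
RAB	642689	A	T	137	28	0	26	IGS	0	0
SHA	642689	A	T	141	43	0	40	IGS	0	0
MOS-A	642689	A	T	157	43	0	42	IGS	0	0
MOS-H	642689	A	T	153	41	0	41	IGS	0	0
DEK	642706	G	T	75	39	0	9	IGS	0	0
SHA	642706	G	T	63	34	0	7	IGS	0	0
SUK-A	642707	A	C	27	39	0	5	IGS	0	0
DEK	642707	A	C	58	39	0	8	IGS	0	0
PER	642707	A	C	24.3	40	0	5	IGS	0	0
SHA	642707	A	C	66	34	0	7	IGS	0	0
MOS-A	642707	A	C	51	37	0	6	IGS	0	0
SUK-A	658617	T	G	222	294	1	263	IGS	0	1
DEK	658617	T	G	218	206	0	188	IGS	0	0
AJW	658617	T	G	222	326	0	290	IGS	0	0
PER	658617	T	G	219	209	0	184	IGS	0	0
SUK-Q	658617	T	G	195	131	0	120	IGS	0	0
RAB	658617	T	G	220	187	0	168	IGS	0	0
SHA	658617	T	G	222	206	0	185	IGS	0	0
MOS-A	658617	T	G	216	180	0	165	IGS	0	0
MOS-H	658617	T	G	222	202	0	187	IGS	0	0
SUK-A	711571	T	G	105	108	0	98	IGS	0	0
DEK	711571	T	G	98	81	0	72	IGS	0	0
AJW	711571	T	G	103	94	0	86	IGS	0	0
PER	711571	T	G	87	72	1	63	IGS	0	1
SUK-Q	711571	T	G	77	38	0	31	IGS	0	0
RAB	711571	T	G	91	45	0	43	IGS	0	0
SHA	711571	T	G,A	79	52	0	45	IGS	0	0
MOS-A	711571	T	G	110	58	0	53	IGS	0	0
MOS-H	711571	T	G	110	70	0	63	IGS	0	0
SUK-A	711576	A	C	120	116	0	104	IGS	0	0
DEK	711576	A	C	115	85	0	80	IGS	0	0
AJW	711576	A	C	111	97	0	90	IGS	0	0
PER	711576	A	C	104	74	0	66	IGS	0	0
SUK-Q	711576	A	C	125	41	0	35	IGS	0	0
RAB	711576	A	C	101	47	0	46	IGS	0	0
SHA	711576	A	C	102	63	0	54	IGS	0	0
MOS-A	711576	A	C	129	61	0	57	IGS	0	0
MOS-H	711576	A	C	121	73	0	66	IGS	0	0
SUK-A	711612	T	G	69	62	0	61	IGS	0	0
DEK	711612	T	G	75	49	0	46	IGS	0	0
AJW	711612	T	G	77	59	0	57	IGS	0	0
PER	711612	T	G	72	46	0	44	IGS	0	0
SUK-Q	711612	T	G	76	20	0	20	IGS	0	0
RAB	711612	T	G	69	25	0	25	IGS	0	0
SHA	711612	T	G	65	38	0	38	IGS	0	0
MOS-A	711612	T	G	87	33	0	32	IGS	0	0
MOS-H	711612	T	G	76	42	0	42	IGS	0	0
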