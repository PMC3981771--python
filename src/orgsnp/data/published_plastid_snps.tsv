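cultivar	position	ref	alt	quality	read_depth	depth_reference	depth_alternate	location	unique	polymorphic
SUK-A	12167	A	C	21	96	9	7	S-atpA	0	0
DEK	12191	A	C	58	134	9	16	S-atpA	0	0
MOS-A	12191	A	C	22	140	13	8	S-atpA	0	0
PER	12191	A	C	44	172	16	16	S-atpA	0	0
SUK-A	12191	A	C	43	199	17	20	S-atpA	0	0
MOS-A	38157	T	G	52	11	4	5	S-psaB	1	0
MOS-A	38160	C	T	36	11	5	5	S-psaB	1	0
MOS-A	38181	A	C	56	13	6	7	S-psaB	1	0
PER	38233	A	G	21	17	11	6	NS-psaB	1	0
PER	38608	G	T	19.1	16	10	6	NS-psaB	1	0
AJW	38634	G	A	36	11	4	7	S-psaB	0	0
MOS-A	38634	G	A	46	11	5	6	S-psaB	0	0
PER	38634	G	A	70	21	11	10	S-psaB	0	0
SUK-A	38634	G	A	55	14	7	7	S-psaB	0	0
PER	38692	T	G	49	11	4	5	NS-psaB	1	0
DEK	40739	G	A	33	27	12	10	NS-psaA	0	0
SHA	40739	G	A	34	15	5	7	NS-psaA	0	0
AJW	40783	C	T	20	22	7	5	S-psaA	1	0
AJW	40785	C	T	33	22	9	5	NS-psaA	0	0
DEK	40785	C	T	27	23	11	6	NS-psaA	0	0
RAB	40785	C	T	19.1	20	11	6	NS-psaA	0	0
MOS-H	40812	C	T	16.1	15	4	5	NS-psaA	1	0
AJW	48066	A	C	23	14	7	6	I-trnL-UAA	1	0
MOS-A	65042	A	G	49	11	4	7	IGS-petA:psbJ	0	0
SUK-A	65042	A	G	15.1	12	4	5	IGS-petA:psbJ	0	0
MOS-A	65045	A	T	22	11	4	7	IGS-petA:psbJ	1	0
MOS-A	65409	C	G	19.1	38	30	7	IGS-petA:psbJ	1	0
SUK-Q	65427	C	T	30	33	25	7	IGS-petA:psbJ	1	0
PER	65453	G	A	58	42	26	13	IGS-petA:psbJ	1	0
RAB	79175	G	T	18.1	22	14	7	I-petD	1	0
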