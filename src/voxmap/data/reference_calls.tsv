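neuron_id	cell_class	VGAT	VAChT	NMDAR	AMPAR	Kainate-R
95	aaIN	0	+	+	0	0
102	aaIN	0	0	+	0	0
115	aaIN	0	0	+	0	0
107	Ambiguous cells	0	0	0	0	0
177	Ambiguous cells	0	0	0	0	0
Ant1	Antenna	0	0	0	0	0
Ant2	Antenna	0	0	0	0	0
134	AntRN	0	+	+	+	0
135	AntRN	0	+	+	+	0
142	AntRN	+	0	+	+	0
143	AntRN	0	0	+	0	0
147	AntRN	+	0	+	+	0
152	AntRN	+	0	+	+	+
153	AntRN	+	0	+	+	+
159	AntRN	+	0	+	+	0
161	AntRN	+	0	+	+	+
120	AntRN	0	0	+	0	0
90	Bipolar prIN	0	0	0	0	0
92	Bipolar prIN	0	0	0	0	0
3	BVIN	0	0	0	0	0
13	BVIN	0	0	0	+	0
16	BVIN	0	0	0	0	0
18	BVIN	0	0	0	+	0
21	BVIN	0	0	0	0	0
22	BVIN	0	0	0	0	0
24	BVIN	0	0	0	+	0
33	BVIN	0	0	0	+	0
41	BVIN	0	0	0	0	0
42	BVIN	0	0	0	+	0
43	BVIN	0	0	0	0	0
46	BVIN	0	0	0	0	0
138	BVIN	0	0	0	0	0
1	cor-ass BVIN	0	0	0	0	0
2	cor-ass BVIN	0	0	0	0	0
15	cor-ass BVIN	0	0	0	0	0
17	cor-ass BVIN	0	0	0	0	0
23	cor-ass BVIN	0	0	0	0	0
38	cor-ass BVIN	0	0	0	0	0
48	cor-ass BVIN	0	0	0	+	0
50	cor-ass BVIN	0	0	0	0	0
55	cor-ass BVIN	0	0	0	+	0
59	cor-ass BVIN	0	0	0	+	0
60	cor-ass BVIN	0	0	0	+	0
62	cor-ass BVIN	0	0	0	0	0
68	cor-ass BVIN	0	0	+	0	0
70	cor-ass BVIN	0	0	0	0	0
73	cor-ass BVIN	0	0	0	+	0
78	cor-ass BVIN	0	0	0	0	0
79	cor-ass BVIN	0	0	+	0	0
coronet1	Coronet	0	0	0	0	0
coronet 10	Coronet	0	0	+	+	0
coronet11	Coronet	0	0	+	+	0
coronet12	Coronet	0	0	0	0	0
coronet13	Coronet	0	0	0	0	0
coronet14	Coronet	0	0	0	0	0
coronet15	Coronet	0	0	0	0	0
coronet16	Coronet	0	0	0	0	0
coronet2	Coronet	0	0	0	+	0
coronet3	Coronet	0	0	0	0	0
coronet4	Coronet	0	0	0	+	0
coronet5	Coronet	0	0	0	0	0
coronet6	Coronet	0	0	0	+	0
coronet7	Coronet	0	0	0	0	0
coronet8	Coronet	0	0	0	0	0
coronet9	Coronet	0	0	+	+	0
109	Eminens	+	0	0	0	0
99	Eminens	+	0	0	0	0
103	Nonsensory RN	+	0	0	0	0
106	Nonsensory RN	0	0	0	+	0
122	Nonsensory RN	+	0	0	0	0
125	Nonsensory RN	0	+	+	+	0
93	Nonsensory RN	0	0	0	+	0
160	PBV PNIN	+	0	0	0	+
162	PBV PNIN	+	0	0	+	+
163	PBV PNIN	+	0	0	0	+
164	PBV PNIN	0	0	0	0	+
20	PNIN	0	0	0	0	0
25	PNIN	0	0	0	0	0
29	PNIN	0	0	0	0	0
30	PNIN	0	0	0	0	0
4	PNIN	0	0	0	0	0
6	PNIN	0	0	0	0	0
85	PNIN	+	0	0	0	0
61	PNIN	+	0	0	0	0
65	PNIN	+	0	0	0	0
88	PNIN	+	0	0	0	0
131	PN RN	+	0	0	0	0
prIII-101	PR (III)	0	0	0	0	0
prIII-110	PR (III)	0	0	0	0	0
prIII-113	PR (III)	0	0	0	0	0
prIII-114	PR (III)	0	0	0	0	0
prIII-6	PR (III)	0	0	0	0	0
prIII-7	PR (III)	0	0	0	0	0
prIII-84	PR (III)	0	0	0	0	0
108	pr-AMG RN	0	0	0	0	0
116	pr-AMG RN	+	0	+	0	0
124	pr-AMG RN	+	0	0	0	0
127	pr-AMG RN	0	0	+	0	0
140	pr-AMG RN	0	+	+	+	0
157	pr-AMG RN	+	0	+	+	0
74	pr-AMG RN	0	0	0	0	0
94	pr-AMG RN	+	0	+	0	0
123	pr-BTN RN	+	0	+	0	0
130	pr-BTN RN	+	0	+	0	0
105	pr-cor RN	0	+	+	+	0
112	pr-cor RN	0	+	+	+	0
119	pr-cor RN	0	+	+	+	0
100	prRN	0	+	+	+	0
121	prRN	0	+	+	+	0
126	prRN	0	+	+	+	0
80	prRN	0	0	0	0	0
86	prRN	0	+	+	+	0
96	prRN	0	+	+	+	0
AMG1	AMG	+	0	0	0	0
AMG2	AMG	+	0	0	0	0
AMG3	AMG	+	0	0	0	0
AMG4	AMG	+	0	0	0	0
AMG5	AMG	0	+	0	0	0
AMG6	AMG	0	0	0	0	0
AMG7	AMG	0	0	0	0	0
ddNL	ddN	0	+	+	+	0
ddNR	ddN	0	+	+	0	0
MGIN1L	MGIN	0	+	+	+	0
MGIN1R	MGIN	0	+	+	0	0
MGIN2L	MGIN	0	+	+	+	0
MGIN2R	MGIN	0	+	+	0	0
MGIN3L	MGIN	0	+	+	+	0
MGIN3R	MGIN	0	+	+	0	0
MN1L	MN	0	+	+	+	0
MN1R	MN	0	+	+	0	0
MN2L	MN	0	+	0	+	0
MN2R	MN	0	+	0	0	0
MN3L	MN	0	+	+	+	0
MN3R	MN	0	+	+	0	0
165	Neck	0	+	+	+	+
166	Neck	0	+	+	0	+
pr1	PR (I)	0	0	0	0	0
pr10	PR (I)	+	0	0	0	0
pr11	PR (I)	0	0	0	0	0
pr12	PR (I)	0	0	0	0	0
pr13	PR (I)	0	0	0	0	0
pr14	PR (I)	0	0	0	0	0
pr15	PR (I)	0	0	0	0	0
pr16	PR (I)	0	0	0	0	0
pr17	PR (I)	0	0	0	0	0
pr18	PR (I)	0	0	0	0	0
pr19	PR (I)	0	0	0	0	0
pr2	PR (I)	0	0	0	0	0
pr20	PR (I)	0	0	0	0	0
pr21	PR (I)	0	0	0	0	0
pr22	PR (I)	0	0	0	0	0
pr23	PR (I)	0	0	0	0	0
pr3	PR (I)	0	0	0	0	0
pr4	PR (I)	0	0	0	0	0
pr5	PR (I)	0	0	0	0	0
pr6	PR (I)	0	0	0	0	0
pr7	PR (I)	0	0	0	0	0
pr8	PR (I)	0	0	0	0	0
pr9	PR (I)	0	0	0	0	0
pr-a	PR (II)	+	0	0	0	0
pr-b	PR (II)	+	0	0	0	0
pr-c	PR (II)	+	0	0	0	0
pr-d	PR (II)	+	0	0	0	0
pr-e	PR (II)	+	0	0	0	0
pr-f	PR (II)	+	0	0	0	0
pr-g	PR (II)	+	0	0	0	0
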