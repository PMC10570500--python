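index	name	subnetwork	rich_club
1	PreCG.L	SMN	0
2	PreCG.R	SMN	0
3	SFGdor.L	FPN	1
4	SFGdor.R	FPN	1
5	ORBsup.L	DMN	0
6	ORBsup.R	DMN	0
7	MFG.L	FPN	0
8	MFG.R	FPN	0
9	ORBmid.L	FPN	0
10	ORBmid.R	FPN	0
11	IFGoperc.L	FPN	0
12	IFGoperc.R	FPN	0
13	IFGtriang.L	FPN	0
14	IFGtriang.R	FPN	0
15	ORBinf.L	FPN	0
16	ORBinf.R	FPN	0
17	ROL.L	SMN	0
18	ROL.R	SMN	0
19	SMA.L	SMN	0
20	SMA.R	SMN	0
21	OLF.L	SCN	0
22	OLF.R	SCN	0
23	SFGmed.L	DMN	0
24	SFGmed.R	DMN	0
25	ORBsupmed.L	DMN	0
26	ORBsupmed.R	DMN	0
27	REC.L	DMN	0
28	REC.R	DMN	0
29	INS.L	SN	1
30	INS.R	SN	1
31	ACG.L	SN	0
32	ACG.R	SN	0
33	DCG.L	SN	0
34	DCG.R	SN	0
35	PCG.L	DMN	0
36	PCG.R	DMN	0
37	HIP.L	DMN	1
38	HIP.R	DMN	1
39	PHG.L	DMN	0
40	PHG.R	DMN	0
41	AMYG.L	SCN	0
42	AMYG.R	SCN	0
43	CAL.L	visual	0
44	CAL.R	visual	0
45	CUN.L	visual	0
46	CUN.R	visual	0
47	LING.L	visual	0
48	LING.R	visual	0
49	SOG.L	visual	0
50	SOG.R	visual	0
51	MOG.L	visual	0
52	MOG.R	visual	0
53	IOG.L	visual	0
54	IOG.R	visual	0
55	FFG.L	visual	0
56	FFG.R	visual	0
57	PoCG.L	SMN	0
58	PoCG.R	SMN	0
59	SPG.L	attention	1
60	SPG.R	attention	1
61	IPL.L	FPN	0
62	IPL.R	FPN	0
63	SMG.L	attention	0
64	SMG.R	attention	0
65	ANG.L	DMN	0
66	ANG.R	DMN	0
67	PCUN.L	DMN	1
68	PCUN.R	DMN	1
69	PCL.L	SMN	0
70	PCL.R	SMN	0
71	CAU.L	SCN	0
72	CAU.R	SCN	0
73	PUT.L	SCN	1
74	PUT.R	SCN	1
75	PAL.L	SCN	0
76	PAL.R	SCN	0
77	THA.L	SCN	1
78	THA.R	SCN	1
79	HES.L	SMN	0
80	HES.R	SMN	0
81	STG.L	SMN	0
82	STG.R	SMN	0
83	TPOsup.L	DMN	0
84	TPOsup.R	DMN	0
85	MTG.L	DMN	0
86	MTG.R	DMN	0
87	TPOmid.L	DMN	0
88	TPOmid.R	DMN	0
89	ITG.L	attention	0
90	ITG.R	attention	0
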