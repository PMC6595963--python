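index	name	abbreviation	hemisphere	topo_class	dmn	assignment
1	Precentral gyrus	PreCG.L	left	anterior	0	inferred
2	Precentral gyrus	PreCG.R	right	anterior	0	inferred
3	Superior frontal gyrus, dorsolateral	SFGdor.L	left	anterior	0	enumerated
4	Superior frontal gyrus, dorsolateral	SFGdor.R	right	anterior	0	enumerated
5	Superior frontal gyrus, orbital part	ORBsup.L	left	anterior	1	enumerated
6	Superior frontal gyrus, orbital part	ORBsup.R	right	anterior	1	enumerated
7	Middle frontal gyrus	MFG.L	left	anterior	0	inferred
8	Middle frontal gyrus	MFG.R	right	anterior	0	inferred
9	Middle frontal gyrus, orbital part	ORBmid.L	left	anterior	1	enumerated
10	Middle frontal gyrus, orbital part	ORBmid.R	right	anterior	1	enumerated
11	Inferior frontal gyrus, opercular part	IFGoperc.L	left	anterior	1	enumerated
12	Inferior frontal gyrus, opercular part	IFGoperc.R	right	anterior	1	inferred
13	Inferior frontal gyrus, triangular part	IFGtriang.L	left	anterior	0	enumerated
14	Inferior frontal gyrus, triangular part	IFGtriang.R	right	anterior	0	inferred
15	Inferior frontal gyrus, orbital part	ORBinf.L	left	anterior	0	enumerated
16	Inferior frontal gyrus, orbital part	ORBinf.R	right	anterior	0	enumerated
17	Rolandic operculum	ROL.L	left	anterior	0	enumerated
18	Rolandic operculum	ROL.R	right	anterior	0	inferred
19	Supplementary motor area	SMA.L	left	anterior	0	enumerated
20	Supplementary motor area	SMA.R	right	anterior	0	enumerated
21	Olfactory cortex	OLF.L	left	anterior	1	enumerated
22	Olfactory cortex	OLF.R	right	anterior	1	inferred
23	Superior frontal gyrus, medial	SFGmed.L	left	anterior	1	enumerated
24	Superior frontal gyrus, medial	SFGmed.R	right	anterior	1	enumerated
25	Superior frontal gyrus, medial orbital	ORBsupmed.L	left	anterior	1	inferred
26	Superior frontal gyrus, medial orbital	ORBsupmed.R	right	anterior	1	enumerated
27	Gyrus rectus	REC.L	left	anterior	1	inferred
28	Gyrus rectus	REC.R	right	anterior	1	enumerated
29	Insula	INS.L	left	anterior	0	enumerated
30	Insula	INS.R	right	anterior	0	inferred
31	Anterior cingulate gyrus	ACG.L	left	anterior	1	inferred
32	Anterior cingulate gyrus	ACG.R	right	anterior	1	inferred
33	Middle cingulate gyrus	DCG.L	left	anterior	1	enumerated
34	Middle cingulate gyrus	DCG.R	right	anterior	1	enumerated
35	Posterior cingulate gyrus	PCG.L	left	posterior	1	inferred
36	Posterior cingulate gyrus	PCG.R	right	posterior	1	inferred
37	Hippocampus	HIP.L	left	subcortical	1	inferred
38	Hippocampus	HIP.R	right	subcortical	1	inferred
39	Parahippocampal gyrus	PHG.L	left	subcortical	1	inferred
40	Parahippocampal gyrus	PHG.R	right	subcortical	1	inferred
41	Amygdala	AMYG.L	left	subcortical	0	inferred
42	Amygdala	AMYG.R	right	subcortical	0	inferred
43	Calcarine fissure	CAL.L	left	posterior	0	inferred
44	Calcarine fissure	CAL.R	right	posterior	0	inferred
45	Cuneus	CUN.L	left	posterior	0	inferred
46	Cuneus	CUN.R	right	posterior	0	inferred
47	Lingual gyrus	LING.L	left	posterior	0	inferred
48	Lingual gyrus	LING.R	right	posterior	0	inferred
49	Superior occipital gyrus	SOG.L	left	posterior	0	inferred
50	Superior occipital gyrus	SOG.R	right	posterior	0	inferred
51	Middle occipital gyrus	MOG.L	left	posterior	0	inferred
52	Middle occipital gyrus	MOG.R	right	posterior	0	inferred
53	Inferior occipital gyrus	IOG.L	left	posterior	0	inferred
54	Inferior occipital gyrus	IOG.R	right	posterior	0	inferred
55	Fusiform gyrus	FFG.L	left	posterior	0	inferred
56	Fusiform gyrus	FFG.R	right	posterior	0	inferred
57	Postcentral gyrus	PoCG.L	left	anterior	0	enumerated
58	Postcentral gyrus	PoCG.R	right	anterior	0	inferred
59	Superior parietal gyrus	SPG.L	left	anterior	1	enumerated
60	Superior parietal gyrus	SPG.R	right	anterior	1	enumerated
61	Inferior parietal lobule	IPL.L	left	anterior	1	enumerated
62	Inferior parietal lobule	IPL.R	right	anterior	1	enumerated
63	Supramarginal gyrus	SMG.L	left	anterior	1	enumerated
64	Supramarginal gyrus	SMG.R	right	anterior	1	inferred
65	Angular gyrus	ANG.L	left	anterior	1	enumerated
66	Angular gyrus	ANG.R	right	anterior	1	enumerated
67	Precuneus	PCUN.L	left	anterior	1	enumerated
68	Precuneus	PCUN.R	right	anterior	1	enumerated
69	Paracentral lobule	PCL.L	left	anterior	0	enumerated
70	Paracentral lobule	PCL.R	right	anterior	0	enumerated
71	Caudate nucleus	CAU.L	left	subcortical	0	inferred
72	Caudate nucleus	CAU.R	right	subcortical	0	inferred
73	Lenticular nucleus, putamen	PUT.L	left	subcortical	0	inferred
74	Lenticular nucleus, putamen	PUT.R	right	subcortical	0	inferred
75	Lenticular nucleus, pallidum	PAL.L	left	subcortical	0	inferred
76	Lenticular nucleus, pallidum	PAL.R	right	subcortical	0	inferred
77	Thalamus	THA.L	left	subcortical	0	inferred
78	Thalamus	THA.R	right	subcortical	0	inferred
79	Heschl gyrus	HES.L	left	posterior	0	inferred
80	Heschl gyrus	HES.R	right	posterior	0	inferred
81	Superior temporal gyrus	STG.L	left	posterior	0	inferred
82	Superior temporal gyrus	STG.R	right	posterior	0	inferred
83	Temporal pole: superior temporal gyrus	TPOsup.L	left	posterior	0	inferred
84	Temporal pole: superior temporal gyrus	TPOsup.R	right	posterior	0	inferred
85	Middle temporal gyrus	MTG.L	left	posterior	1	inferred
86	Middle temporal gyrus	MTG.R	right	posterior	1	inferred
87	Temporal pole: middle temporal gyrus	TPOmid.L	left	posterior	1	inferred
88	Temporal pole: middle temporal gyrus	TPOmid.R	right	posterior	1	inferred
89	Inferior temporal gyrus	ITG.L	left	posterior	0	inferred
90	Inferior temporal gyrus	ITG.R	right	posterior	0	inferred
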