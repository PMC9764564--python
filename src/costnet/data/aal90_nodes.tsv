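index	abbreviation	name	x	y	z
1	PreCG.L	Precentral gyrus (L)	-39	-6	51
2	PreCG.R	Precentral gyrus (R)	41	-8	52
3	SFGdor.L	Superior frontal gyrus, dorsolateral (L)	-18	35	42
4	SFGdor.R	Superior frontal gyrus, dorsolateral (R)	22	31	44
5	ORBsup.L	Superior frontal gyrus, orbital part (L)	-17	47	-13
6	ORBsup.R	Superior frontal gyrus, orbital part (R)	18	48	-14
7	MFG.L	Middle frontal gyrus (L)	-33	33	35
8	MFG.R	Middle frontal gyrus (R)	38	33	34
9	ORBmid.L	Middle frontal gyrus, orbital part (L)	-31	50	-10
10	ORBmid.R	Middle frontal gyrus, orbital part (R)	33	53	-11
11	IFGoperc.L	Inferior frontal gyrus, opercular part (L)	-48	13	19
12	IFGoperc.R	Inferior frontal gyrus, opercular part (R)	50	15	21
13	IFGtriang.L	Inferior frontal gyrus, triangular part (L)	-46	30	14
14	IFGtriang.R	Inferior frontal gyrus, triangular part (R)	50	30	14
15	ORBinf.L	Inferior frontal gyrus, orbital part (L)	-36	31	-12
16	ORBinf.R	Inferior frontal gyrus, orbital part (R)	41	32	-12
17	ROL.L	Rolandic operculum (L)	-47	-8	14
18	ROL.R	Rolandic operculum (R)	53	-6	15
19	SMA.L	Supplementary motor area (L)	-5	5	61
20	SMA.R	Supplementary motor area (R)	9	0	62
21	OLF.L	Olfactory cortex (L)	-8	15	-11
22	OLF.R	Olfactory cortex (R)	10	16	-11
23	SFGmed.L	Superior frontal gyrus, medial (L)	-5	49	31
24	SFGmed.R	Superior frontal gyrus, medial (R)	9	51	30
25	ORBsupmed.L	Superior frontal gyrus, medial orbital (L)	-5	54	-7
26	ORBsupmed.R	Superior frontal gyrus, medial orbital (R)	8	51	-7
27	REC.L	Gyrus rectus (L)	-5	37	-18
28	REC.R	Gyrus rectus (R)	8	36	-18
29	INS.L	Insula (L)	-35	7	3
30	INS.R	Insula (R)	39	6	2
31	ACG.L	Anterior cingulate and paracingulate gyri (L)	-4	35	14
32	ACG.R	Anterior cingulate and paracingulate gyri (R)	8	37	16
33	DCG.L	Median cingulate and paracingulate gyri (L)	-5	-15	42
34	DCG.R	Median cingulate and paracingulate gyri (R)	8	-9	40
35	PCG.L	Posterior cingulate gyrus (L)	-5	-43	25
36	PCG.R	Posterior cingulate gyrus (R)	7	-42	22
37	HIP.L	Hippocampus (L)	-25	-21	-10
38	HIP.R	Hippocampus (R)	29	-20	-10
39	PHG.L	Parahippocampal gyrus (L)	-21	-16	-21
40	PHG.R	Parahippocampal gyrus (R)	25	-15	-20
41	AMYG.L	Amygdala (L)	-23	-1	-17
42	AMYG.R	Amygdala (R)	27	1	-18
43	CAL.L	Calcarine fissure and surrounding cortex (L)	-7	-79	6
44	CAL.R	Calcarine fissure and surrounding cortex (R)	16	-73	9
45	CUN.L	Cuneus (L)	-6	-80	27
46	CUN.R	Cuneus (R)	14	-79	28
47	LING.L	Lingual gyrus (L)	-15	-68	-5
48	LING.R	Lingual gyrus (R)	16	-67	-4
49	SOG.L	Superior occipital gyrus (L)	-17	-84	28
50	SOG.R	Superior occipital gyrus (R)	24	-81	31
51	MOG.L	Middle occipital gyrus (L)	-32	-81	16
52	MOG.R	Middle occipital gyrus (R)	37	-80	19
53	IOG.L	Inferior occipital gyrus (L)	-36	-78	-8
54	IOG.R	Inferior occipital gyrus (R)	38	-82	-8
55	FFG.L	Fusiform gyrus (L)	-31	-40	-20
56	FFG.R	Fusiform gyrus (R)	34	-39	-20
57	PoCG.L	Postcentral gyrus (L)	-42	-23	49
58	PoCG.R	Postcentral gyrus (R)	41	-25	53
59	SPG.L	Superior parietal gyrus (L)	-23	-60	59
60	SPG.R	Superior parietal gyrus (R)	26	-59	62
61	IPL.L	Inferior parietal, supramarginal and angular gyri (L)	-43	-46	47
62	IPL.R	Inferior parietal, supramarginal and angular gyri (R)	46	-46	50
63	SMG.L	Supramarginal gyrus (L)	-56	-34	30
64	SMG.R	Supramarginal gyrus (R)	58	-32	34
65	ANG.L	Angular gyrus (L)	-44	-61	36
66	ANG.R	Angular gyrus (R)	46	-60	39
67	PCUN.L	Precuneus (L)	-7	-56	48
68	PCUN.R	Precuneus (R)	10	-56	44
69	PCL.L	Paracentral lobule (L)	-8	-25	70
70	PCL.R	Paracentral lobule (R)	7	-32	68
71	CAU.L	Caudate nucleus (L)	-11	11	9
72	CAU.R	Caudate nucleus (R)	15	12	9
73	PUT.L	Lenticular nucleus, putamen (L)	-23	4	2
74	PUT.R	Lenticular nucleus, putamen (R)	28	5	2
75	PAL.L	Lenticular nucleus, pallidum (L)	-18	0	0
76	PAL.R	Lenticular nucleus, pallidum (R)	21	0	0
77	THA.L	Thalamus (L)	-11	-18	8
78	THA.R	Thalamus (R)	13	-18	8
79	HES.L	Heschl gyrus (L)	-42	-19	10
80	HES.R	Heschl gyrus (R)	46	-17	10
81	STG.L	Superior temporal gyrus (L)	-53	-21	7
82	STG.R	Superior temporal gyrus (R)	58	-21	7
83	TPOsup.L	Temporal pole: superior temporal gyrus (L)	-40	15	-20
84	TPOsup.R	Temporal pole: superior temporal gyrus (R)	48	15	-17
85	MTG.L	Middle temporal gyrus (L)	-56	-34	-2
86	MTG.R	Middle temporal gyrus (R)	57	-37	-1
87	TPOmid.L	Temporal pole: middle temporal gyrus (L)	-36	15	-34
88	TPOmid.R	Temporal pole: middle temporal gyrus (R)	44	15	-32
89	ITG.L	Inferior temporal gyrus (L)	-50	-28	-23
90	ITG.R	Inferior temporal gyrus (R)	54	-31	-22
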