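index,name,abbreviation,hemisphere,lobe_tags,partner_abbreviation
0,Precentral gyrus,PreCG,L,frontal;central,PreCG
1,Precentral gyrus,PreCG,R,frontal;central,PreCG
2,Superior frontal gyrus (dorsolateral),SFGdor,L,frontal,SFGdor
3,Superior frontal gyrus (dorsolateral),SFGdor,R,frontal,SFGdor
4,Superior frontal gyrus (orbital),ORBsup,L,frontal,ORBsup
5,Superior frontal gyrus (orbital),ORBsup,R,frontal,ORBsup
6,Middle frontal gyrus,MFG,L,frontal,MFG
7,Middle frontal gyrus,MFG,R,frontal,MFG
8,Middle frontal gyrus (orbital),ORBmid,L,frontal,ORBmid
9,Middle frontal gyrus (orbital),ORBmid,R,frontal,ORBmid
10,Inferior frontal gyrus (opercular),IFGoperc,L,frontal,IFGoperc
11,Inferior frontal gyrus (opercular),IFGoperc,R,frontal,IFGoperc
12,Inferior frontal gyrus (triangular),IFGtriang,L,frontal,IFGtriang
13,Inferior frontal gyrus (triangular),IFGtriang,R,frontal,IFGtriang
14,Inferior frontal gyrus (orbital),ORBinf,L,frontal,ORBinf
15,Inferior frontal gyrus (orbital),ORBinf,R,frontal,ORBinf
16,Rolandic operculum,ROL,L,frontal;central,ROL
17,Rolandic operculum,ROL,R,frontal;central,ROL
18,Supplementary motor area,SMA,L,frontal,SMA
19,Supplementary motor area,SMA,R,frontal,SMA
20,Olfactory cortex,OLF,L,frontal,OLF
21,Olfactory cortex,OLF,R,frontal,OLF
22,Superior frontal gyrus (medial),SFGmed,L,frontal,SFGmed
23,Superior frontal gyrus (medial),SFGmed,R,frontal,SFGmed
24,Superior frontal gyrus (medial orbital),ORBsupmed,L,frontal,ORBsupmed
25,Superior frontal gyrus (medial orbital),ORBsupmed,R,frontal,ORBsupmed
26,Rectus gyrus,REC,L,frontal,REC
27,Rectus gyrus,REC,R,frontal,REC
28,Insula,INS,L,limbic,INS
29,Insula,INS,R,limbic,INS
30,Anterior cingulate gyrus,ACG,L,limbic,ACG
31,Anterior cingulate gyrus,ACG,R,limbic,ACG
32,Median cingulate gyrus,MCG,L,limbic,MCG
33,Median cingulate gyrus,MCG,R,limbic,MCG
34,Posterior cingulate gyrus,PCG,L,limbic,PCG
35,Posterior cingulate gyrus,PCG,R,limbic,PCG
36,Hippocampus,HIP,L,limbic,HIP
37,Hippocampus,HIP,R,limbic,HIP
38,Parahippocampal gyrus,PHG,L,limbic,PHG
39,Parahippocampal gyrus,PHG,R,limbic,PHG
40,Amygdala,AMYG,L,limbic;subcortical,AMYG
41,Amygdala,AMYG,R,limbic;subcortical,AMYG
42,Calcarine cortex,CAL,L,occipital,CAL
43,Calcarine cortex,CAL,R,occipital,CAL
44,Cuneus,CUN,L,occipital,CUN
45,Cuneus,CUN,R,occipital,CUN
46,Lingual gyrus,LING,L,occipital,LING
47,Lingual gyrus,LING,R,occipital,LING
48,Superior occipital gyrus,SOG,L,occipital,SOG
49,Superior occipital gyrus,SOG,R,occipital,SOG
50,Middle occipital gyrus,MOG,L,occipital,MOG
51,Middle occipital gyrus,MOG,R,occipital,MOG
52,Inferior occipital gyrus,IOG,L,occipital,IOG
53,Inferior occipital gyrus,IOG,R,occipital,IOG
54,Fusiform gyrus,FFG,L,temporal,FFG
55,Fusiform gyrus,FFG,R,temporal,FFG
56,Postcentral gyrus,PoCG,L,parietal;central,PoCG
57,Postcentral gyrus,PoCG,R,parietal;central,PoCG
58,Superior parietal gyrus,SPG,L,parietal,SPG
59,Superior parietal gyrus,SPG,R,parietal,SPG
60,Inferior parietal gyrus,IPG,L,parietal,IPG
61,Inferior parietal gyrus,IPG,R,parietal,IPG
62,Supramarginal gyrus,SMG,L,parietal,SMG
63,Supramarginal gyrus,SMG,R,parietal,SMG
64,Angular gyrus,ANG,L,parietal,ANG
65,Angular gyrus,ANG,R,parietal,ANG
66,Precuneus,PCUN,L,parietal,PCUN
67,Precuneus,PCUN,R,parietal,PCUN
68,Paracentral lobule,PCL,L,parietal,PCL
69,Paracentral lobule,PCL,R,parietal,PCL
70,Caudate,CAU,L,subcortical,CAU
71,Caudate,CAU,R,subcortical,CAU
72,Putamen,PUT,L,subcortical,PUT
73,Putamen,PUT,R,subcortical,PUT
74,Pallidum,PAL,L,subcortical,PAL
75,Pallidum,PAL,R,subcortical,PAL
76,Thalamus,THA,L,subcortical,THA
77,Thalamus,THA,R,subcortical,THA
78,Heschl gyrus,HES,L,temporal,HES
79,Heschl gyrus,HES,R,temporal,HES
80,Superior temporal gyrus,STG,L,temporal,STG
81,Superior temporal gyrus,STG,R,temporal,STG
82,Temporal pole (superior),TPOsup,L,temporal,TPOsup
83,Temporal pole (superior),TPOsup,R,temporal,TPOsup
84,Middle temporal gyrus,MTG,L,temporal,MTG
85,Middle temporal gyrus,MTG,R,temporal,MTG
86,Temporal pole (middle),TPOmid,L,temporal,TPOmid
87,Temporal pole (middle),TPOmid,R,temporal,TPOmid
88,Inferior temporal gyrus,ITG,L,temporal,ITG
89,Inferior temporal gyrus,ITG,R,temporal,ITG
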