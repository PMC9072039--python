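index,name,abbreviation,hemisphere,system
0,Left precentral gyrus,PreCG.L,L,other
1,Right precentral gyrus,PreCG.R,R,other
2,"Left superior frontal gyrus, dorsolateral",SFGdor.L,L,other
3,"Right superior frontal gyrus, dorsolateral",SFGdor.R,R,other
4,"Left superior frontal gyrus, orbital part",ORBsup.L,L,other
5,"Right superior frontal gyrus, orbital part",ORBsup.R,R,other
6,Left middle frontal gyrus,MFG.L,L,other
7,Right middle frontal gyrus,MFG.R,R,other
8,"Left middle frontal gyrus, orbital part",ORBmid.L,L,other
9,"Right middle frontal gyrus, orbital part",ORBmid.R,R,other
10,"Left inferior frontal gyrus, opercular part",IFGoperc.L,L,other
11,"Right inferior frontal gyrus, opercular part",IFGoperc.R,R,other
12,"Left inferior frontal gyrus, triangular part",IFGtriang.L,L,other
13,"Right inferior frontal gyrus, triangular part",IFGtriang.R,R,other
14,"Left inferior frontal gyrus, orbital part",ORBinf.L,L,other
15,"Right inferior frontal gyrus, orbital part",ORBinf.R,R,other
16,Left rolandic operculum,ROL.L,L,other
17,Right rolandic operculum,ROL.R,R,other
18,Left supplementary motor area,SMA.L,L,other
19,Right supplementary motor area,SMA.R,R,other
20,Left olfactory cortex,OLF.L,L,other
21,Right olfactory cortex,OLF.R,R,other
22,"Left superior frontal gyrus, medial",SFGmed.L,L,other
23,"Right superior frontal gyrus, medial",SFGmed.R,R,other
24,"Left superior frontal gyrus, medial orbital",ORBsupmed.L,L,other
25,"Right superior frontal gyrus, medial orbital",ORBsupmed.R,R,other
26,Left rectus gyrus,REC.L,L,other
27,Right rectus gyrus,REC.R,R,other
28,Left insula,INS.L,L,other
29,Right insula,INS.R,R,other
30,Left anterior cingulate and paracingulate gyri,ACG.L,L,other
31,Right anterior cingulate and paracingulate gyri,ACG.R,R,other
32,Left median cingulate and paracingulate gyri,MCG.L,L,other
33,Right median cingulate and paracingulate gyri,MCG.R,R,other
34,Left posterior cingulate gyrus,PCG.L,L,default-mode
35,Right posterior cingulate gyrus,PCG.R,R,default-mode
36,Left hippocampus,HIP.L,L,other
37,Right hippocampus,HIP.R,R,other
38,Left parahippocampal gyrus,PHG.L,L,limbic
39,Right parahippocampal gyrus,PHG.R,R,limbic
40,Left amygdala,AMYG.L,L,other
41,Right amygdala,AMYG.R,R,other
42,Left calcarine fissure and surrounding cortex,CAL.L,L,visual
43,Right calcarine fissure and surrounding cortex,CAL.R,R,visual
44,Left cuneus,CUN.L,L,visual
45,Right cuneus,CUN.R,R,visual
46,Left lingual gyrus,LING.L,L,visual
47,Right lingual gyrus,LING.R,R,visual
48,Left superior occipital gyrus,SOG.L,L,visual
49,Right superior occipital gyrus,SOG.R,R,visual
50,Left middle occipital gyrus,MOG.L,L,other
51,Right middle occipital gyrus,MOG.R,R,other
52,Left inferior occipital gyrus,IOG.L,L,visual
53,Right inferior occipital gyrus,IOG.R,R,visual
54,Left fusiform gyrus,FG.L,L,visual
55,Right fusiform gyrus,FG.R,R,visual
56,Left postcentral gyrus,PoCG.L,L,other
57,Right postcentral gyrus,PoCG.R,R,other
58,Left superior parietal gyrus,SPG.L,L,other
59,Right superior parietal gyrus,SPG.R,R,other
60,Left inferior parietal lobule,IPL.L,L,other
61,Right inferior parietal lobule,IPL.R,R,other
62,Left supramarginal gyrus,SMG.L,L,other
63,Right supramarginal gyrus,SMG.R,R,other
64,Left angular gyrus,ANG.L,L,other
65,Right angular gyrus,ANG.R,R,other
66,Left precuneus,PCUN.L,L,default-mode
67,Right precuneus,PCUN.R,R,default-mode
68,Left paracentral lobule,PCL.L,L,other
69,Right paracentral lobule,PCL.R,R,other
70,Left caudate nucleus,CAU.L,L,other
71,Right caudate nucleus,CAU.R,R,other
72,"Left lenticular nucleus, putamen",PUT.L,L,other
73,"Right lenticular nucleus, putamen",PUT.R,R,other
74,"Left lenticular nucleus, pallidum",PAL.L,L,other
75,"Right lenticular nucleus, pallidum",PAL.R,R,other
76,Left thalamus,THA.L,L,other
77,Right thalamus,THA.R,R,other
78,Left heschl gyrus,HES.L,L,other
79,Right heschl gyrus,HES.R,R,other
80,Left superior temporal gyrus,STG.L,L,other
81,Right superior temporal gyrus,STG.R,R,other
82,Left temporal pole: superior temporal gyrus,TPOsup.L,L,other
83,Right temporal pole: superior temporal gyrus,TPOsup.R,R,other
84,Left middle temporal gyrus,MTG.L,L,other
85,Right middle temporal gyrus,MTG.R,R,other
86,Left temporal pole: middle temporal gyrus,TPOmid.L,L,other
87,Right temporal pole: middle temporal gyrus,TPOmid.R,R,other
88,Left inferior temporal gyrus,ITG.L,L,other
89,Right inferior temporal gyrus,ITG.R,R,other
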