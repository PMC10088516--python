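branch_id,branch_name,chunk_id,chunk_name
1,BA proximal trunk,1,BA
2,BA mid trunk,1,BA
3,BA distal trunk,1,BA
4,Lt ICA cavernous,2,Lt ICA
5,Lt ICA clinoid,2,Lt ICA
6,Lt ICA ophthalmic,2,Lt ICA
7,Lt ICA communicating,2,Lt ICA
8,Lt Pcom,2,Lt ICA
9,Rt ICA cavernous,3,Rt ICA
10,Rt ICA clinoid,3,Rt ICA
11,Rt ICA ophthalmic,3,Rt ICA
12,Rt ICA communicating,3,Rt ICA
13,Rt Pcom,3,Rt ICA
14,Lt ACA A1,4,Lt basal ACA
15,Lt ACA A2,4,Lt basal ACA
16,Acom,4,Lt basal ACA
17,Rt ACA A1,5,Rt basal ACA
18,Rt ACA A2,5,Rt basal ACA
19,Lt MCA M1 proximal,6,Lt basal MCA
20,Lt MCA M1 distal,6,Lt basal MCA
21,Lt MCA M2 superior,6,Lt basal MCA
22,Lt MCA M2 inferior,6,Lt basal MCA
23,Lt MCA anterior temporal,6,Lt basal MCA
24,Rt MCA M1 proximal,7,Rt basal MCA
25,Rt MCA M1 distal,7,Rt basal MCA
26,Rt MCA M2 superior,7,Rt basal MCA
27,Rt MCA M2 inferior,7,Rt basal MCA
28,Rt MCA anterior temporal,7,Rt basal MCA
29,Lt PCA P1,8,Lt basal PCA
30,Lt PCA P2,8,Lt basal PCA
31,Rt PCA P1,9,Rt basal PCA
32,Rt PCA P2,9,Rt basal PCA
33,Lt pericallosal A3,10,Lt pial ACA
34,Lt pericallosal A4,10,Lt pial ACA
35,Lt callosomarginal,10,Lt pial ACA
36,Lt frontopolar,10,Lt pial ACA
37,Rt pericallosal A3,11,Rt pial ACA
38,Rt pericallosal A4,11,Rt pial ACA
39,Rt callosomarginal,11,Rt pial ACA
40,Rt frontopolar,11,Rt pial ACA
41,Lt MCA M3,12,Lt pial MCA
42,Lt MCA M4 prefrontal,12,Lt pial MCA
43,Lt MCA M4 precentral,12,Lt pial MCA
44,Lt MCA M4 central,12,Lt pial MCA
45,Lt MCA M4 parietal,12,Lt pial MCA
46,Lt MCA M4 angular,12,Lt pial MCA
47,Rt MCA M3,13,Rt pial MCA
48,Rt MCA M4 prefrontal,13,Rt pial MCA
49,Rt MCA M4 precentral,13,Rt pial MCA
50,Rt MCA M4 central,13,Rt pial MCA
51,Rt MCA M4 parietal,13,Rt pial MCA
52,Rt MCA M4 angular,13,Rt pial MCA
53,Lt PCA P3,14,Lt pial PCA
54,Lt PCA P4,14,Lt pial PCA
55,Lt parieto-occipital,14,Lt pial PCA
56,Lt calcarine,14,Lt pial PCA
57,Lt posterior temporal,14,Lt pial PCA
58,Rt PCA P3,15,Rt pial PCA
59,Rt PCA P4,15,Rt pial PCA
60,Rt parieto-occipital,15,Rt pial PCA
61,Rt calcarine,15,Rt pial PCA
62,Rt posterior temporal,15,Rt pial PCA
63,Lt SCA,16,Lt cbll
64,Lt AICA,16,Lt cbll
65,Lt PICA,16,Lt cbll
66,Lt cbll hemispheric,16,Lt cbll
67,Rt SCA,17,Rt cbll
68,Rt AICA,17,Rt cbll
69,Rt PICA,17,Rt cbll
70,Rt cbll hemispheric,17,Rt cbll
71,Lt VA V4 proximal,18,Lt VA
72,Lt VA V4 distal,18,Lt VA
73,Rt VA V4 proximal,19,Rt VA
74,Rt VA V4 distal,19,Rt VA
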