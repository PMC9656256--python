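index,label,x,y,z
1,Precentral_L,-51.1,-44.4,15.7
2,Precentral_R,26.0,-93.9,-39.9
3,Frontal_Sup_2_L,-8.0,-90.4,-37.2
4,Frontal_Sup_2_R,9.5,-76.0,54.3
5,Frontal_Mid_2_L,-30.0,-5.0,-32.6
6,Frontal_Mid_2_R,53.6,16.9,50.4
7,Frontal_Inf_Oper_L,-14.1,-47.2,-26.7
8,Frontal_Inf_Oper_R,42.0,-89.5,62.6
9,Frontal_Inf_Tri_L,-13.5,-39.4,8.1
10,Frontal_Inf_Tri_R,25.1,-2.2,26.0
11,Frontal_Inf_Orb_2_L,-33.1,-41.3,45.4
12,Frontal_Inf_Orb_2_R,24.3,52.5,-23.6
13,Rolandic_Oper_L,-48.1,2.0,38.3
14,Rolandic_Oper_R,21.7,20.1,-35.6
15,Supp_Motor_Area_L,-39.2,-33.4,-18.0
16,Supp_Motor_Area_R,43.8,-90.9,32.0
17,Olfactory_L,-25.2,-7.1,-14.7
18,Olfactory_R,50.0,-60.3,57.7
19,Frontal_Sup_Medial_L,-36.7,7.5,44.3
20,Frontal_Sup_Medial_R,17.1,-32.1,48.4
21,Frontal_Med_Orb_L,-45.4,-86.8,20.5
22,Frontal_Med_Orb_R,26.8,24.4,59.4
23,Rectus_L,-36.9,-25.8,23.2
24,Rectus_R,22.5,32.9,35.7
25,OFCmed_L,-11.6,-33.1,45.0
26,OFCmed_R,22.4,9.0,54.5
27,OFCant_L,-10.7,-37.3,21.8
28,OFCant_R,34.6,-24.9,-43.4
29,OFCpost_L,-33.7,-58.2,3.7
30,OFCpost_R,40.2,-86.5,45.9
31,OFClat_L,-54.2,-51.2,-1.1
32,OFClat_R,39.1,56.1,47.4
33,Insula_L,-5.7,-2.9,30.1
34,Insula_R,19.6,-51.4,61.8
35,Cingulate_Mid_L,-53.2,6.6,34.4
36,Cingulate_Mid_R,10.6,19.0,53.1
37,Cingulate_Post_L,-14.8,21.5,-12.1
38,Cingulate_Post_R,23.3,-58.2,-6.9
39,Hippocampus_L,-41.2,36.2,-26.1
40,Hippocampus_R,29.0,18.6,-40.3
41,ParaHippocampal_L,-28.4,29.1,-24.9
42,ParaHippocampal_R,15.3,-94.5,-29.9
43,Amygdala_L,-51.2,36.3,-5.0
44,Amygdala_R,41.6,-44.9,-12.6
45,Calcarine_L,-42.1,47.0,37.2
46,Calcarine_R,44.3,56.8,-20.6
47,Cuneus_L,-46.7,31.2,-35.0
48,Cuneus_R,30.1,-43.6,-8.6
49,Lingual_L,-52.9,-15.9,48.2
50,Lingual_R,29.9,57.4,46.1
51,Occipital_Sup_L,-18.6,-35.4,38.8
52,Occipital_Sup_R,54.1,-80.5,42.8
53,Occipital_Mid_L,-9.8,11.9,-34.3
54,Occipital_Mid_R,8.6,7.3,56.7
55,Occipital_Inf_L,-13.2,-12.9,11.5
56,Occipital_Inf_R,44.3,-44.6,-3.2
57,Fusiform_L,-42.0,-59.0,51.2
58,Fusiform_R,31.5,-80.2,-0.1
59,Postcentral_L,-17.6,49.6,-27.5
60,Postcentral_R,9.8,-13.7,-42.7
61,Parietal_Sup_L,-32.8,-28.3,-29.7
62,Parietal_Sup_R,31.6,36.6,0.9
63,Parietal_Inf_L,-50.4,-76.6,-2.1
64,Parietal_Inf_R,25.9,-20.0,59.7
65,SupraMarginal_L,-53.2,-86.8,23.2
66,SupraMarginal_R,15.0,47.7,35.5
67,Angular_L,-38.4,27.3,-24.8
68,Angular_R,40.6,-86.2,13.2
69,Precuneus_L,-19.1,-61.2,9.4
70,Precuneus_R,15.7,-39.9,-7.5
71,Paracentral_Lobule_L,-21.2,-3.1,-25.0
72,Paracentral_Lobule_R,33.2,-31.1,43.8
73,Caudate_L,-46.7,-29.5,60.2
74,Caudate_R,12.2,39.2,61.2
75,Putamen_L,-46.6,-3.2,-12.1
76,Putamen_R,48.6,9.7,27.5
77,Pallidum_L,-10.3,-72.2,32.4
78,Pallidum_R,5.7,-14.7,59.8
79,Heschl_L,-13.6,-91.8,19.7
80,Heschl_R,30.9,33.3,59.2
81,Temporal_Sup_L,-6.9,26.4,-22.8
82,Temporal_Sup_R,9.2,26.9,-9.7
83,Temporal_Pole_Sup_L,-27.9,-28.8,56.3
84,Temporal_Pole_Sup_R,33.9,-10.3,62.5
85,Temporal_Mid_L,-22.1,-65.0,-22.7
86,Temporal_Mid_R,30.2,-18.6,52.9
87,Temporal_Pole_Mid_L,-38.9,-87.0,32.7
88,Temporal_Pole_Mid_R,40.6,-75.4,-9.9
89,Temporal_Inf_L,-10.7,29.4,33.4
90,Temporal_Inf_R,20.6,0.4,47.7
91,Cerebellum_Crus1_L,-22.6,-4.5,-2.9
92,Cerebellum_Crus1_R,9.3,-65.0,-38.7
93,Cerebellum_Crus2_L,-44.4,13.6,-22.1
94,Cerebellum_Crus2_R,7.7,-67.5,-18.1
95,Cerebellum_3_L,-29.1,47.4,-2.6
96,Cerebellum_3_R,27.4,-57.9,-38.6
97,Cerebellum_4_5_L,-28.9,59.0,-7.3
98,Cerebellum_4_5_R,35.2,-4.0,3.8
99,Cerebellum_6_L,-22.0,-88.1,42.8
100,Cerebellum_6_R,44.0,-88.2,-15.3
101,Cerebellum_7b_L,-26.7,34.4,26.6
102,Cerebellum_7b_R,41.4,-94.8,31.1
103,Cerebellum_8_L,-13.0,-64.9,55.4
104,Cerebellum_8_R,5.0,-88.2,-5.3
105,Cerebellum_9_L,-41.2,8.9,1.4
106,Cerebellum_9_R,20.7,7.5,49.7
107,Cerebellum_10_L,-52.1,-6.1,51.9
108,Cerebellum_10_R,44.1,-80.0,-7.9
109,Vermis_1_2,-0.4,42.7,1.3
110,Vermis_3,3.0,-90.8,17.7
111,Vermis_4_5,-1.8,-80.7,-8.1
112,Vermis_6,-2.1,17.6,-21.4
113,Vermis_7,1.0,52.6,6.1
114,Vermis_8,2.8,-28.1,30.0
115,Vermis_9,-1.1,-72.1,46.4
116,Vermis_10,0.1,-86.4,-6.6
117,Thal_AV_L,-43.4,-35.5,20.6
118,Thal_AV_R,41.6,-94.0,25.4
119,Thal_LP_L,-30.1,38.0,13.1
120,Thal_LP_R,52.2,-57.5,26.1
121,Thal_VA_L,-16.4,57.5,13.3
122,Thal_VA_R,7.4,18.0,34.8
123,Thal_VL_L,-12.8,-93.3,-1.0
124,Thal_VL_R,37.9,12.9,-17.4
125,Thal_VPL_L,-52.9,-31.0,56.8
126,Thal_VPL_R,31.7,33.5,43.7
127,Thal_IL_L,-27.4,36.6,35.7
128,Thal_IL_R,52.3,-61.7,50.1
129,Thal_Re_L,-42.2,-44.1,-39.8
130,Thal_Re_R,47.7,45.1,-30.6
131,Thal_MDm_L,-7.5,-66.6,30.1
132,Thal_MDm_R,27.5,50.7,14.5
133,Thal_MDl_L,-32.3,-85.6,8.0
134,Thal_MDl_R,17.3,30.8,22.3
135,Thal_LGN_L,-44.3,-12.1,-1.8
136,Thal_LGN_R,6.3,-58.3,18.9
137,Thal_MGN_L,-28.3,29.8,27.4
138,Thal_MGN_R,37.6,-56.0,8.0
139,Thal_PuA_L,-40.8,-41.2,47.0
140,Thal_PuA_R,37.5,3.4,-27.9
141,Thal_PuM_L,-43.2,-72.7,2.1
142,Thal_PuM_R,26.6,41.7,-42.6
143,Thal_PuL_L,-16.1,-7.9,-10.4
144,Thal_PuL_R,28.9,-52.9,33.4
145,Thal_PuI_L,-15.4,19.7,-26.8
146,Thal_PuI_R,49.9,43.4,-0.2
147,ACC_sub_L,-39.2,-81.2,39.4
148,ACC_sub_R,27.7,-53.5,59.6
149,ACC_pre_L,-18.2,-17.8,46.4
150,ACC_pre_R,5.7,-55.1,41.3
151,ACC_sup_L,-46.3,15.8,50.4
152,ACC_sup_R,13.2,-54.7,55.2
153,N_Acc_L,-17.4,-61.1,48.4
154,N_Acc_R,37.2,-51.5,-6.2
155,VTA_L,-12.4,31.4,16.5
156,VTA_R,39.4,-57.9,-16.5
157,SN_pc_L,-47.6,38.2,-30.6
158,SN_pc_R,42.0,-76.5,51.5
159,SN_pr_L,-51.1,54.3,32.3
160,SN_pr_R,16.9,19.2,-6.0
161,Red_N_L,-42.0,15.9,-37.7
162,Red_N_R,47.5,2.0,15.5
163,LC_L,-21.3,7.3,59.4
164,LC_R,17.6,13.7,-41.3
165,Raphe_D,-2.8,15.8,-30.7
166,Raphe_M,-1.0,-10.1,32.7
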