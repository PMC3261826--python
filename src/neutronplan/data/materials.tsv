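# id	name	density_g_cm3	state	comp_type	composition
# comp_type "mass": element:mass-fraction pairs; "atom": element:integer-ratio pairs.
# Tissue compositions are ICRU-44 / ICRP-89 style values; see PROVENANCE.md.
0	vacuum	0.0	gas	atom	-
1	water	1.000	solid	atom	H:2,O:1
2	perspex	1.19	solid	atom	C:5,O:2,H:8
3	aluminum	2.699	solid	atom	Al:1
4	concrete	2.300	solid	mass	H:0.022100,C:0.002484,O:0.574931,Na:0.015208,Mg:0.001266,Al:0.019953,Si:0.304627,K:0.010045,Ca:0.042951,Fe:0.006435
5	air	0.0012048	gas	mass	C:0.000124,N:0.755268,O:0.231781,Ar:0.012827
10	soft_tissue	1.03	solid	mass	H:0.102,C:0.143,N:0.034,O:0.708,Na:0.002,P:0.003,S:0.003,Cl:0.002,K:0.003
11	brain	1.04	solid	mass	H:0.107,C:0.145,N:0.022,O:0.712,Na:0.002,P:0.004,S:0.002,Cl:0.003,K:0.003
12	blood	1.06	solid	mass	H:0.102,C:0.110,N:0.033,O:0.745,Na:0.001,P:0.001,S:0.002,Cl:0.003,K:0.002,Fe:0.001
13	lung_inflated	0.26	solid	mass	H:0.103,C:0.105,N:0.031,O:0.749,Na:0.002,P:0.002,S:0.003,Cl:0.003,K:0.002
14	cartilage	1.10	solid	mass	H:0.096,C:0.099,N:0.022,O:0.744,Na:0.005,P:0.022,S:0.009,Cl:0.003
15	eye_lens	1.07	solid	mass	H:0.096,C:0.195,N:0.057,O:0.646,Na:0.001,P:0.001,S:0.003,Cl:0.001
16	thyroid	1.05	solid	mass	H:0.104,C:0.119,N:0.024,O:0.745,Na:0.002,P:0.001,S:0.001,Cl:0.002,K:0.001,I:0.001
17	mucosa	1.05	solid	mass	H:0.106,C:0.097,N:0.022,O:0.761,Na:0.004,P:0.004,S:0.002,Cl:0.003,K:0.001
18	spinal_cord	1.04	solid	mass	H:0.107,C:0.145,N:0.022,O:0.712,Na:0.002,P:0.004,S:0.002,Cl:0.003,K:0.003
19	skin	1.09	solid	mass	H:0.100,C:0.204,N:0.042,O:0.645,Na:0.002,P:0.001,S:0.002,Cl:0.003,K:0.001
20	salivary_gland	1.03	solid	mass	H:0.102,C:0.143,N:0.034,O:0.708,Na:0.002,P:0.003,S:0.003,Cl:0.002,K:0.003
21	muscle	1.05	solid	mass	H:0.102,C:0.143,N:0.034,O:0.710,Na:0.001,P:0.002,S:0.003,Cl:0.001,K:0.004
22	heart	1.05	solid	mass	H:0.104,C:0.139,N:0.029,O:0.718,Na:0.001,P:0.002,S:0.002,Cl:0.002,K:0.003
23	cortical_bone	1.92	solid	mass	H:0.035,C:0.160,N:0.042,O:0.445,Na:0.003,Mg:0.002,P:0.095,S:0.003,Ca:0.215
24	spongiosa	1.18	solid	mass	H:0.085,C:0.404,N:0.028,O:0.367,Na:0.002,Mg:0.001,P:0.034,S:0.002,Cl:0.002,K:0.001,Ca:0.074
25	red_marrow	1.03	solid	mass	H:0.105,C:0.414,N:0.034,O:0.439,P:0.001,S:0.002,Cl:0.002,K:0.002,Fe:0.001
26	yellow_marrow	0.98	solid	mass	H:0.115,C:0.644,N:0.007,O:0.231,Na:0.001,S:0.001,Cl:0.001
27	breast	1.02	solid	mass	H:0.106,C:0.332,N:0.030,O:0.527,Na:0.001,P:0.001,S:0.002,Cl:0.001
28	adipose	0.95	solid	mass	H:0.114,C:0.598,N:0.007,O:0.278,Na:0.001,S:0.001,Cl:0.001
29	liver	1.06	solid	mass	H:0.102,C:0.139,N:0.030,O:0.716,Na:0.002,P:0.003,S:0.003,Cl:0.002,K:0.003
30	kidney	1.05	solid	mass	H:0.103,C:0.132,N:0.030,O:0.724,Na:0.002,P:0.002,S:0.002,Cl:0.002,K:0.002,Ca:0.001
31	spleen	1.06	solid	mass	H:0.103,C:0.113,N:0.032,O:0.741,Na:0.001,P:0.003,S:0.002,Cl:0.002,K:0.003
32	pancreas	1.04	solid	mass	H:0.106,C:0.169,N:0.022,O:0.694,Na:0.002,P:0.002,S:0.001,Cl:0.002,K:0.002
33	oesophagus	1.03	solid	mass	H:0.106,C:0.115,N:0.022,O:0.751,Na:0.001,P:0.001,S:0.001,Cl:0.002,K:0.001
34	teeth	2.20	solid	mass	H:0.022,C:0.095,N:0.029,O:0.421,Mg:0.007,P:0.137,Ca:0.289
35	csf	1.01	solid	mass	H:0.111,O:0.880,Na:0.005,Cl:0.004
36	lymph	1.03	solid	mass	H:0.108,C:0.041,N:0.011,O:0.832,Na:0.003,S:0.001,Cl:0.004
37	tongue	1.05	solid	mass	H:0.102,C:0.143,N:0.034,O:0.710,Na:0.001,P:0.002,S:0.003,Cl:0.001,K:0.004
38	pituitary	1.03	solid	mass	H:0.105,C:0.093,N:0.024,O:0.768,Na:0.002,P:0.002,S:0.002,Cl:0.002,K:0.002
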