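mutation	ddg_fold	sd	delta_e	provenance
L1152P	11.06	0.024	-5.84	resistance_primary
I1171T	3.07	0.026	-2.72	resistance_primary
I1171N	3.18	0.030	-4.94	resistance_primary
I1171S	2.83	0.009	-4.54	resistance_primary
F1174C	4.22	0.027	-6.24	resistance_primary
F1174S	5.14	0.069	-7.26	resistance_primary
V1180L	0.96	0.027	-3.98	resistance_primary
L1198F	-1.19	0.024	-4.14	resistance_primary
S1206C	3.23	0.350	-5.28	resistance_primary
L1152R	3.17	0.409	-4.86	resistance_secondary
C1156Y	4.47	0.634	-4.41	resistance_secondary
F1174L	1.36	0.185	-2.54	resistance_secondary
L1196M	-0.16	0.039	-4.82	resistance_secondary
L1198P	1.46	0.058	-7.18	resistance_secondary
G1202R	2.88	0.140	-5.76	resistance_secondary
D1203N	3.85	0.149	-4.46	resistance_secondary
S1206Y	2.72	0.236	-5.64	resistance_secondary
G1269A	0.52	0.376	-1.41	resistance_secondary
G1269S	2.92	0.556	-1.72	resistance_secondary
E1210K/S1206C	-1.02	0.273	-8.25	resistance_secondary
E1210K/D1203N	0.90	0.215	-7.78	resistance_secondary
L1198F/C1156Y	-0.26	0.449	-9.17	resistance_secondary
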