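gene_id	fold_change_log2	sd	family_group
VvAP2-3	14.02		AP2
VvERF036	11.17		ERF-IV
VvERF051	10.04		ERF-V
VvAP2-5	8.97		AP2
VvAP2-16	8.71		AP2
VvERF94	8.39		ERF-IX
VvERF102	8.34		ERF-IX
VvERF098	8.19	0.83	ERF-IX
VvERF020	8.12		ERF-III
VvERF042	7.53		ERF-V
VvERF111	7.17	1.95	ERF-IX
VvAP2-10	6.37		AP2
VvERF067	6.22		ERF-VIII
VvERF103	5.91		ERF-IX
VvERF077	5.79	1.78	ERF-IX
VvERF093	5.67	2.06	ERF-IX
VvERF038	5.28	1.58	ERF-IV
VvERF097	5.24	2.31	ERF-IX
VvERF017	5.21	2.69	ERF-III
VvERF120	5.18	0.59	ERF-X
VvERF070	5.02	0.62	ERF-VIII
VvERF142	4.58	0.55	RAV
VvAP2-17	4.04	1.5	AP2
VvERF086	3.93	1.68	ERF-IX
VvERF074	3.59	1.94	ERF-IX
VvERF032	3.59	0.7	ERF-III
VvERF040	3.37	1	ERF-IV
VvERF072	3.35		ERF-IX
VvERF060	3.33		ERF-VIII
VvERF087	2.08		ERF-IX
VvERF109	2.03	0.39	ERF-IX
VvERF001	-8.6	2.62	ERF-I
VvERF018	-5.87		ERF-III
VvERF141	-5.35	3.24	RAV
VvERF002	-4.86	2.25	ERF-I
VvERF012	-4.46	2.21	ERF-III
VvERF104	-4.4	3.74	ERF-IX
VvERF055	-4.35	3.48	ERF-VI
VvERF044	-3.61	2.51	ERF-V
VvERF082	-3.6	2.14	ERF-IX
VvERF092	-3.55	0.92	ERF-IX
VvERF028	-3.38	2.64	ERF-III
VvERF084	-3.29	1.16	ERF-IX
VvAP2-14	-3.15		AP2
VvERF108	-2.82	1.36	ERF-IX
VvAP2-20	-2.71	1.7	AP2
VvERF071	-2.7	0.68	ERF-IX
VvERF105	-2.45	1.72	ERF-IX
VvERF035	-2.24		ERF-III
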