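gene_id	fold_change_log2	sd	family_group
VvERF046	6.46	0.65	ERF-V
VvERF118	5.31	1.87	ERF-X
VvERF047	5.2	0.64	ERF-V
VvERF027	4.69		ERF-III
VvERF053	4.5	3.5	ERF-VI
VvERF072	4.27	1.61	ERF-IX
VvERF071	4.14	1.66	ERF-IX
VvERF023	4	0.81	ERF-III
VvERF092	3.45	1.88	ERF-IX
VvAP2-13	3.35	1.35	AP2
VvERF095	3.13	1.09	ERF-IX
VvAP2-8	3.13	0.39	AP2
VvAP2-3	3.05		AP2
VvERF094	2.81	1.81	ERF-IX
VvERF103	2.56		ERF-IX
VvERF045	2.47	2.23	ERF-V
VvERF006	2.45	1.35	ERF-II
VvAP2-12	2.3	1.74	AP2
VvERF114	-14.37		ERF-X
VvERF146	-7.94		RAV
VvERF100	-7.3		ERF-IX
VvERF107	-6.48		ERF-IX
VvAP2-1	-6.07		AP2
VvERF099	-5.85	5.29	ERF-IX
VvERF085	-5.64	2.69	ERF-IX
VvERF106	-5.23	0.89	ERF-IX
VvAP2-5	-4.9		AP2
VvERF097	-4.71		ERF-IX
VvERF010	-4.64	2.29	ERF-II
VvERF029	-4.54	4.02	ERF-III
VvERF022	-4.44	1.46	ERF-III
VvERF111	-3.96	0.03	ERF-IX
VvAP2-17	-3.83	1.85	AP2
VvAP2-16	-3.53		AP2
VvERF020	-3.51		ERF-III
VvERF054	-3.49	0.08	ERF-VI
VvERF087	-3.49		ERF-IX
VvERF079	-3.25	2.53	ERF-IX
VvERF096	-3.16	2.47	ERF-IX
VvERF016	-3.13	2.01	ERF-III
VvERF05	-3.12	2.4	ERF-I
VvERF122	-3	1.09	ERF-6-L
VvERF117	-2.81	0.6	ERF-X
VvERF024	-2.42	1.07	ERF-III
VvERF040	-2.38	0.41	ERF-IV
VvERF051	-2.34	0.96	ERF-V
VvERF098	-2.21	1.47	ERF-IX
VvERF018	-2.09		ERF-III
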