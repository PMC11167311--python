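name	auc	tpr	precision	accuracy	mcc	f1	pos_num	neg_num
P20309	0.93	0.88	0.92	0.88	0.76	0.90	664	478
P35372	0.91	0.84	0.86	0.85	0.71	0.85	1054	1077
P61169	0.86	0.85	0.69	0.79	0.58	0.76	529	805
P19327	0.82	0.77	0.86	0.76	0.49	0.81	948	451
O43613	0.79	0.65	0.49	0.76	0.41	0.56	226	734
P33533	0.77	0.84	0.75	0.73	0.42	0.79	609	399
P25099	0.77	0.47	0.51	0.81	0.37	0.49	199	813
P41144	0.76	0.84	0.74	0.72	0.39	0.79	552	352
Q99705	0.72	0.48	0.71	0.65	0.31	0.57	450	483
P33535	0.68	0.72	0.75	0.65	0.23	0.74	913	443
P29275	0.67	0.19	0.23	0.77	0.07	0.21	147	794
P32245	0.65	0.40	0.57	0.63	0.20	0.47	404	575
P50406	0.58	0.22	0.87	0.41	0.15	0.35	913	339
Q9Y5N1	0.55	0.25	0.89	0.32	0.03	0.39	1308	201
P0DMS8	0.52	0.16	0.55	0.60	0.10	0.25	566	805
P21554	0.48	0.30	0.36	0.61	0.05	0.32	571	1238
ALL	0.72	0.73	0.73	0.68	0.37	0.64	10053	9987
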