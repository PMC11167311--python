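name	rmse	mse	pearson	spearman	prmsd	total_num
P20309	1.35	1.82	0.65	0.69	0.19	2006
P35372	1.19	1.41	0.57	0.56	0.17	4236
P25099	1.19	1.42	0.49	0.48	0.19	2932
P33533	1.35	1.82	0.48	0.47	0.19	1969
P41144	1.31	1.71	0.46	0.44	0.18	2173
P32245	1.37	1.88	0.42	0.37	0.20	2613
P61169	1.16	1.35	0.42	0.41	0.17	4460
P33535	1.53	2.36	0.38	0.37	0.22	2962
O43613	1.22	1.49	0.35	0.33	0.19	3811
Q9Y5N1	1.34	1.80	0.34	0.32	0.18	3693
Q99705	1.25	1.56	0.31	0.25	0.18	3610
P19327	1.26	1.59	0.29	0.29	0.18	4632
P0DMS8	1.46	2.13	0.26	0.27	0.22	3797
P29275	1.26	1.59	0.18	0.14	0.19	1804
P50406	1.62	2.63	0.12	0.09	0.22	3297
P21554	1.59	2.53	0.11	0.10	0.24	3530
Average	1.34	1.80	0.39	0.35	0.19	51525
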