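compound_id	bc_score	rg_score	docking_score
S948-0241	1.00	9.39	-7.61
K297-0698	1.00	9.08	-7.37
C301-4662	1.00	9.11	-7.19
V011-4148	1.00	9.76	-7.06
V026-2353	1.00	9.26	-6.78
G219-1242	1.00	9.56	-6.74
F545-1970	1.00	9.01	-6.74
E216-0947	1.00	9.25	-6.74
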