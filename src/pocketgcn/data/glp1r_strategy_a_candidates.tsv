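compound_id	rg_score	bc_score	docking_score
V027-3795	9.68	1.00	-9.14
V012-1447	9.53	1.00	-9.52
V009-0856	9.55	1.00	-8.82
V005-2405	9.55	1.00	-8.80
S978-0648	9.70	1.00	-8.82
C875-0922	9.56	1.00	-9.00
G818-0282	9.73	1.00	-9.03
S954-5266	9.67	1.00	-9.11
C700-1841	9.56	1.00	-9.45
SB04-0468	9.56	1.00	-9.58
Y043-3164	9.76	1.00	-8.83
T158-1384	9.64	1.00	-8.89
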