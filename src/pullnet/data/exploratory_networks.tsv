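network_id	size	n_metabolites	metabolites	seed_q
c1_3_65	14	7	myristate (14:0);palmitate (16:0);linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*;margarate (17:0);sphingomyelin (d18:1/17:0, d17:1/18:0, d19:1/16:0);laurate (12:0)	4.20E-04
c1_3_14	105	7	(14 or 15)-methylpalmitate (a17:0 or i17:0);caprate (10:0);laurate (12:0);myristoylcarnitine (C14);sphingomyelin (d18:1/17:0, d17:1/18:0, d19:1/16:0);myristate (14:0);palmitate (16:0)	1.72E-02
c2_4_461	60	7	3-hydroxybutyrate (BHBA);caprate (10:0);histidine;myristate (14:0);palmitate (16:0);laurate (12:0);margarate (17:0)	2.29E-05
c1_3_67	82	6	cysteine;linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*;margarate (17:0);myristate (14:0);palmitate (16:0)	3.77E-07
c1_3_43	57	6	caprate (10:0);histidine;myristate (14:0);palmitate (16:0);laurate (12:0);margarate (17:0)	7.99E-05
c1_3_63	5	6	caprate (10:0);linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*;margarate (17:0);myristate (14:0);palmitate (16:0)	3.87E-02
c2_4_552	8	5	2’-deoxycytidine;uridine;margarate (17:0);myristate (14:0);palmitate (16:0)	2.96E-05
c2_4_464	38	5	linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*;margarate (17:0);myristate (14:0);palmitate (16:0)	1.83E-04
c2_4_463	9	5	myristate (14:0);palmitate (16:0);linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*;margarate (17:0)	1.30E-02
c2_4_418	10	5	linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*;margarate (17:0);myristate (14:0);palmitate (16:0)	1.71E-02
c1_3_71	95	5	caprate (10:0);margarate (17:0);laurate (12:0);myristate (14:0);palmitate (16:0)	2.65E-02
c1_3_91	13	5	caprate (10:0);laurate (12:0);myristate (14:0);palmitate (16:0);margarate (17:0)	2.66E-02
c1_3_117	29	5	caprate (10:0);margarate (17:0);laurate (12:0);myristate (14:0);palmitate (16:0)	3.87E-02
c1_3_70	193	5	linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*;palmitate (16:0); 2-aminobutyrate; 1-(1-enyl-palmitoyl)-2-oleoyl-GPC (P-16:0/18:1)*	1.26E-03
c1_3_62	6	4	histidine;laurate (12:0);linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*	1.90E-04
c1_3_112	24	4	caprate (10:0);laurate (12:0);myristate (14:0);palmitate (16:0)	2.36E-02
c1_3_111	5	4	adenine;myristate (14:0);margarate (17:0);palmitate (16:0)	3.87E-02
c1_3_116	66	3	histidine;linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*	2.59E-07
c2_4_457	112	3	caprate (10:0);linoleoyl-arachidonoyl-glycerol (18:2/20:4) [2]*;linoleoyl-linoleoyl-glycerol (18:2/18:2) [1]*	1.01E-02
c1_3_80	19	3	3-hydroxybutyrate (BHBA);caprate (10:0);laurate (12:0)	1.30E-02
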