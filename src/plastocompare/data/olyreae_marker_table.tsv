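locus	length_min	length_max	aligned_length	n_vc	pct_vc	n_pic	pct_pic
trnD(GUC)-psbM	854	1064	1177	276	23.45	139	11.81
rpl32-trnL(UAG)	612	753	820	147	17.93	53	6.46
ycf4-cemA	408	457	477	83	17.40	27	5.66
psbK-psbI	385	400	413	71	17.19	30	7.26
psbZ-trnfM(CAU)	462	818	946	159	16.81	61	6.45
trnT(GGU)-trnE(UUC)	463	493	542	91	16.79	24	4.43
rbcL-psaI	1117	1219	1347	224	16.63	82	6.09
trnF(GAA)-ndhJ	442	604	631	103	16.32	36	5.71
trnK(UUU)-rps16	380	563	595	97	16.30	26	4.37
rps16-trnQ(UUG)	721	1091	1252	202	16.13	60	4.79
petA-psbJ	956	988	1065	167	15.68	56	5.26
atpH-atpF	421	456	476	73	15.34	15	3.15
trnS(GCU)-psbD	866	982	1077	165	15.32	60	5.57
psaA-ycf3	583	640	736	110	14.95	32	4.35
ycf3-trnS(GGA)	535	595	621	91	14.65	38	6.12
trnT(UGU)-trnL(UAA)	733	785	853	122	14.30	45	5.28
rpl16 intron	1046	1117	1150	164	14.26	52	4.52
psaC-ndhE	462	513	592	83	14.02	30	5.07
ndhC-trnV(UAC)	777	917	1036	142	13.71	50	4.83
ndhA intron	1002	1017	1067	143	13.40	44	4.12
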