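district	area_km2	pyrethroid_g	kdr_frequency_pct	f1534s_frequency_pct
Fengxian	687.39	32999.52	0.00	0.00
Qingpu	670.14	223195.10	46.81	25.53
Chongming	1185.49	254808.10	82.89	44.08
Pudong	1210.41	133659.00	87.80	68.90
Yangpu	60.73	27640.00	86.96	50.00
Hongkou	23.48	141026.60	88.10	72.62
Jiading	464.20	84737.20	95.00	71.25
Songjiang	605.64	16250.00	95.24	67.86
Changning	38.30	62000.00	97.50	72.50
Xuhui	54.76	21250.00	100.00	88.75
Putuo	54.83	89900.00	100.00	91.89
Minhang	370.75	25173.00	100.00	75.00
Jinshan	586.05	47506.00	100.00	82.05
Jingan	36.88	30679.00	100.00	80.00
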