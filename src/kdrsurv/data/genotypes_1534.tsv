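code	n	TTC	TTT	TCC	TGC	ATC	F/F	F/S	S/C	S/I	S/S	C/C
FX	37	100.00	0.00	0.00	0.00	0.00	100.00	0.00	0.00	0.00	0.00	0.00
QP	47	74.47	0.00	25.53	0.00	0.00	55.32	38.30	0.00	0.00	6.38	0.00
CM	38	81.58	0.00	18.42	0.00	0.00	65.79	31.58	0.00	0.00	2.63	0.00
PD	45	36.67	0.00	58.89	4.44	0.00	26.67	20.00	0.00	0.00	48.89	4.44
YP	46	50.00	0.00	50.00	0.00	0.00	26.09	47.83	0.00	0.00	26.09	0.00
HK	42	27.38	0.00	72.62	0.00	0.00	16.67	21.43	0.00	0.00	61.90	0.00
JD	40	28.75	0.00	71.25	0.00	0.00	4.44	47.50	0.00	0.00	47.50	0.00
SJ	42	28.57	2.38	67.86	1.19	0.00	16.67	28.57	2.38	0.00	52.38	0.00
YH	37	16.22	0.00	81.08	0.00	2.70	2.70	27.03	0.00	5.41	64.86	0.00
CX	38	30.26	0.00	69.74	0.00	0.00	18.42	23.68	0.00	0.00	57.89	0.00
CN	40	27.50	0.00	72.50	0.00	0.00	10.00	35.00	0.00	0.00	55.00	0.00
XH	40	11.25	0.00	88.75	0.00	0.00	2.50	17.50	0.00	0.00	80.00	0.00
PT	37	8.11	0.00	91.89	0.00	0.00	0.00	16.22	0.00	0.00	83.78	0.00
MH	40	25.00	0.00	75.00	0.00	0.00	2.50	45.00	0.00	0.00	52.50	0.00
JS	39	17.95	0.00	82.05	0.00	0.00	5.13	25.64	0.00	0.00	69.23	0.00
JA	50	11.00	0.00	80.00	9.00	0.00	2.00	18.00	18.00	0.00	62.00	0.00
Total	658	35.87	0.15	62.77	1.06	0.15	22.04	27.96	1.52	0.30	47.87	0.30
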