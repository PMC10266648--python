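code	n	GTA	GGA	V/V	V/G	G/G
FX	37	100.00	0.00	100.00	0.00	0.00
QP	47	100.00	0.00	100.00	0.00	0.00
CM	38	82.89	17.11	71.25	23.68	5.26
PD	45	95.56	4.44	91.11	8.89	0.00
YP	46	92.39	7.61	84.78	15.22	0.00
HK	42	95.24	4.76	92.86	4.76	2.38
JD	40	92.50	7.50	85.00	15.00	0.00
SJ	42	85.71	14.29	73.81	23.81	2.38
YH	37	95.95	4.05	91.89	8.11	0.00
CX	38	88.16	11.84	76.32	23.68	0.00
CN	40	88.75	11.25	77.50	22.50	0.00
XH	40	100.00	0.00	100.00	0.00	0.00
PT	37	95.95	4.05	91.89	8.11	0.00
MH	40	95.00	5.00	90.00	10.00	0.00
JS	39	91.03	8.97	84.62	12.82	2.56
JA	50	93.00	7.00	88.00	10.00	2.00
Total	658	92.86	7.14	86.63	12.46	0.91
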