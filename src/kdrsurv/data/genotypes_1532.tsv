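code	n	ATC	ACC	I/I	I/T	T/T
FX	37	100.00	0.00	100.00	0.00	0.00
QP	47	97.87	2.13	95.74	4.26	0.00
CM	38	90.79	9.21	86.84	7.89	5.26
PD	45	97.78	2.22	95.56	4.44	0.00
YP	46	93.48	6.52	86.96	13.04	0.00
HK	42	98.81	1.19	97.62	2.38	0.00
JD	40	98.89	1.11	97.78	2.22	0.00
SJ	42	96.43	3.57	92.86	7.14	0.00
YH	37	95.95	4.05	91.89	8.11	0.00
CX	38	94.74	5.26	92.11	5.26	2.63
CN	40	93.75	6.25	87.50	12.50	0.00
XH	40	95.00	5.00	90.00	10.00	0.00
PT	37	98.65	1.35	97.30	2.70	0.00
MH	40	96.25	3.75	92.50	7.50	0.00
JS	39	98.72	1.28	97.44	2.56	0.00
JA	50	98.00	2.00	96.00	4.00	0.00
Total	658	96.58	3.42	93.62	5.93	0.46
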