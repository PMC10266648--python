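code	n	mutation_frequency_pct
FX	37	0.00
QP	47	46.81
CM	38	68.42
PD	45	80.00
YP	46	86.96
HK	42	88.10
JD	40	95.00
SJ	42	95.24
YH	37	97.30
CX	38	97.37
CN	40	97.50
XH	40	100.00
PT	37	100.00
MH	40	100.00
JS	39	100.00
JA	50	100.00
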