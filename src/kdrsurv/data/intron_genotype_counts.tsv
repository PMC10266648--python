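intron	I/I+F/F	I/I+F/S	I/I+S/S	I/I+S/C	I/I+C/C	I/T+F/F	I/T+F/S	T/T+F/F
A	67	6	3	0	0	1	0	0
B	53	149	306	10	0	12	24	3
C	1	0	0	0	0	0	0	0
D	1	0	0	0	0	0	0	0
E	1	0	0	0	1	0	0	0
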