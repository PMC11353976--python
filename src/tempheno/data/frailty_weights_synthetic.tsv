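icd10	points
F00	7.1
G81	4.4
G30	4.0
I69	3.7
R29	3.6
N39	3.2
F05	3.2
W19	3.2
S00	3.2
R31	3.0
B96	2.9
R41	2.7
R26	2.6
I67	2.6
R56	2.6
R40	2.5
T83	2.4
S06	2.4
S42	2.3
E87	2.3
M25	2.3
E86	2.3
R54	2.2
Z50	2.1
F03	2.1
W18	2.1
Z75	2.0
F01	2.0
W14	1.9
S22	1.8
K59	1.8
N17	1.8
L89	1.7
Z22	1.7
B95	1.7
L97	1.6
R44	1.6
K26	1.6
I95	1.6
N19	1.6
A41	1.6
Z87	1.5
J96	1.5
X59	1.5
M19	1.4
G40	1.4
M81	1.4
S72	1.4
S32	1.4
E16	1.4
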