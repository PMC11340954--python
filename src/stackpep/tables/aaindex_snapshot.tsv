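index	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
KYTJ820101	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
HOPT810101	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
GRAR740102	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
ZIMJ680104	6.00	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.66	5.96	5.89	5.66
SIDECHAIN_MASS	15.0	47.0	59.0	73.0	91.0	1.0	82.0	57.0	73.0	57.0	75.0	58.0	42.0	72.0	101.0	31.0	45.0	43.0	130.0	107.0
SANDBERG_Z1	0.24	0.84	3.98	3.11	-4.22	2.05	2.47	-3.89	2.29	-4.28	-2.85	3.05	-1.66	1.75	3.52	2.39	0.75	-2.59	-4.36	-2.54
SANDBERG_Z2	-2.32	-1.67	0.93	0.26	1.94	-4.06	1.95	-1.73	0.89	-1.30	-0.22	1.62	0.27	0.50	2.50	-1.07	-2.18	-2.64	3.94	2.44
SANDBERG_Z3	0.60	3.71	1.93	-0.11	1.06	0.36	0.26	-1.71	-2.49	-1.49	0.47	1.04	1.84	-1.44	-3.50	1.15	-1.12	-1.54	0.59	0.43
SANDBERG_Z4	-0.14	0.18	-2.46	-3.04	0.54	-0.82	3.90	-0.84	1.49	-0.72	1.94	-1.15	0.70	-1.34	1.99	-1.39	-1.46	-0.85	3.44	0.04
SANDBERG_Z5	1.30	-2.65	0.75	-0.25	-0.62	-0.38	0.09	0.26	0.31	0.84	-0.98	1.61	2.00	0.66	-0.17	0.67	-0.40	-0.02	-1.59	-1.47
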