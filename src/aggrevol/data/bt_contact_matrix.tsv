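	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.20	-0.26	0.30	0.43	-0.33	-0.03	0.21	-0.35	0.20	-0.37	-0.23	0.24	0.07	0.21	0.27	0.15	0.00	-0.38	-0.40	-0.15
C	-0.26	-1.34	0.38	0.46	-0.53	-0.09	-0.19	-0.48	0.35	-0.50	-0.49	0.28	-0.18	0.04	0.32	0.09	0.00	-0.51	-0.74	-0.16
D	0.30	0.38	0.27	0.40	0.48	0.17	-0.22	0.54	-0.69	0.62	0.62	-0.12	0.25	0.12	-0.71	0.01	0.00	0.66	0.06	-0.07
E	0.43	0.46	0.40	0.45	0.34	0.48	-0.11	0.38	-0.87	0.37	0.24	-0.01	0.26	0.10	-0.75	0.10	0.00	0.41	-0.15	-0.16
F	-0.33	-0.53	0.48	0.34	-0.82	0.11	-0.19	-0.65	0.11	-0.78	-0.89	0.29	-0.19	-0.04	0.08	0.10	0.00	-0.67	-0.78	-0.49
G	-0.03	-0.09	0.17	0.48	0.11	-0.20	0.23	0.21	0.12	0.14	0.08	0.10	-0.01	0.20	0.14	0.10	0.00	0.04	-0.24	-0.04
H	0.21	-0.19	-0.22	-0.11	-0.19	0.23	-0.33	0.19	0.26	0.10	-0.17	0.10	-0.05	0.22	0.04	0.15	0.00	0.18	-0.46	-0.21
I	-0.35	-0.48	0.54	0.38	-0.65	0.21	0.19	-0.60	0.21	-0.79	-0.60	0.55	0.05	0.14	0.18	0.35	0.00	-0.68	-0.65	-0.33
K	0.20	0.35	-0.69	-0.87	0.11	0.12	0.26	0.21	0.38	0.16	0.22	-0.14	0.12	-0.20	0.50	0.10	0.00	0.16	-0.28	-0.40
L	-0.37	-0.50	0.62	0.37	-0.78	0.14	0.10	-0.79	0.16	-0.81	-0.68	0.36	-0.08	0.08	0.09	0.26	0.00	-0.80	-0.70	-0.44
M	-0.23	-0.49	0.62	0.24	-0.89	0.08	-0.17	-0.60	0.22	-0.68	-0.56	0.32	-0.16	-0.01	0.17	0.32	0.00	-0.47	-0.94	-0.51
N	0.24	0.28	-0.12	-0.01	0.29	0.10	0.10	0.55	-0.14	0.36	0.32	-0.04	0.13	-0.05	0.02	0.14	0.00	0.39	-0.09	0.01
P	0.07	-0.18	0.25	0.26	-0.19	-0.01	-0.05	0.05	0.12	-0.08	-0.16	0.13	-0.07	-0.05	-0.02	0.17	0.00	-0.08	-0.73	-0.40
Q	0.21	0.04	0.12	0.10	-0.04	0.20	0.22	0.14	-0.20	0.08	-0.01	-0.05	-0.05	0.14	-0.12	0.25	0.00	0.17	-0.11	-0.18
R	0.27	0.32	-0.71	-0.75	0.08	0.14	0.04	0.18	0.50	0.09	0.17	0.02	-0.02	-0.12	0.13	0.12	0.00	0.17	-0.41	-0.37
S	0.15	0.09	0.01	0.10	0.10	0.10	0.15	0.35	0.10	0.26	0.32	0.14	0.17	0.25	0.12	0.13	0.00	0.25	0.07	0.07
T	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
V	-0.38	-0.51	0.66	0.41	-0.67	0.04	0.18	-0.68	0.16	-0.80	-0.47	0.39	-0.08	0.17	0.17	0.25	0.00	-0.72	-0.62	-0.27
W	-0.40	-0.74	0.06	-0.15	-0.78	-0.24	-0.46	-0.65	-0.28	-0.70	-0.94	-0.09	-0.73	-0.11	-0.41	0.07	0.00	-0.62	-0.74	-0.55
Y	-0.15	-0.16	-0.07	-0.16	-0.49	-0.04	-0.21	-0.33	-0.40	-0.44	-0.51	0.01	-0.40	-0.18	-0.37	0.07	0.00	-0.27	-0.55	-0.27
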