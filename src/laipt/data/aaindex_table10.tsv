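property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
CHOP780207	0.52	0.94	1.06	0.59	1.04	1.64	1.86	0.87	1.49	0.84	0.52	1.64	1.58	0.70	1.24	0.93	0.86	0.32	0.16	0.96
DAYM780201	100	20	106	102	41	49	66	96	56	40	94	134	56	93	65	120	97	74	18	41
EISD860102	0.00	0.17	1.90	3.00	1.10	0.00	0.99	1.20	5.70	1.00	1.90	1.30	0.18	1.90	10.00	0.73	1.50	0.48	1.60	1.80
FAUJ880108	-0.01	0.12	0.15	0.07	0.03	0.00	0.08	-0.01	0.00	-0.01	0.04	0.06	0.00	0.05	0.04	0.11	0.04	0.01	0.00	0.03
FAUJ880111	0	0	0	0	0	0	1	0	1	0	0	0	0	0	1	0	0	0	0	0
FINA910103	1.2	1.0	0.7	0.7	1.0	0.8	1.2	0.8	1.7	1.0	1.0	1.2	1.0	1.0	1.7	1.5	1.0	0.8	1.0	1.0
JANJ780101	27.8	15.5	60.6	68.2	25.5	24.5	50.7	22.8	103.0	27.6	33.5	60.1	51.5	68.7	94.7	42.0	45.0	23.7	34.7	55.2
KARP850103	0.892	0.925	0.932	0.933	0.914	0.923	0.894	0.872	1.057	0.921	0.804	0.930	0.932	0.885	0.901	0.923	0.934	0.913	0.803	0.837
KLEP840101	0	0	-1	-1	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0
KRIW710101	4.60	-1.00	5.70	5.60	3.20	7.60	4.50	2.60	7.90	3.25	1.40	5.90	7.00	6.10	6.50	5.25	4.80	3.40	4.00	4.35
KRIW790102	0.28	0.11	0.33	0.37	0.10	0.28	0.23	0.12	0.59	0.16	0.08	0.31	0.46	0.39	0.34	0.27	0.26	0.22	0.15	0.25
NAKH920103	5.15	3.24	5.75	7.05	3.52	6.38	2.69	4.40	5.25	8.11	1.60	4.81	5.65	4.45	4.38	8.04	7.41	7.00	1.68	3.42
QIAN880101	0.12	-0.25	0.01	-0.02	0.05	-0.02	-0.06	-0.07	0.26	0.05	0.00	-0.10	-0.19	-0.03	0.04	-0.19	-0.04	-0.03	-0.06	-0.14
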