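# Grantham (1974) amino-acid distance matrix, integer-rounded.
# Upper triangle; rows/cols are one-letter residue codes.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A		195	126	107	113	60	85	94	106	96	84	110	27	91	111	99	58	64	148	112
C			154	169	204	158	174	197	202	197	196	139	169	154	180	112	149	191	214	194
D				45	177	94	81	168	101	172	160	23	108	61	96	65	85	152	191	160
E					140	98	41	134	57	138	126	41	94	29	54	80	66	121	152	123
F						153	100	21	102	22	29	158	114	116	97	155	103	50	40	22
G							98	135	126	138	127	79	42	87	125	55	59	109	184	147
H								94	32	99	86	68	76	24	29	89	47	84	115	83
I									102	5	10	149	95	109	98	142	89	30	61	33
K										106	94	94	103	53	26	121	78	97	109	85
L											14	152	98	112	102	144	92	32	61	36
M												141	87	101	92	135	81	22	67	35
N													90	46	85	46	65	133	174	142
P														75	103	73	38	68	147	110
Q															43	68	41	96	130	99
R																109	71	96	101	77
S																	58	123	177	143
T																		69	128	92
V																			88	55
W																				37
Y																				
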