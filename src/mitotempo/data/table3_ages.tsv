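event	prior_soares	prior_soares_lo	prior_soares_hi	prior_fu	prior_fu_lo	prior_fu_hi	prior_rieux	prior_rieux_lo	prior_rieux_hi	prior_demographic	prior_demographic_lo	prior_demographic_hi	soares_kyr	soares_lo	soares_hi	amtdna_kyr	amtdna_lo	amtdna_hi
MtEva	192	152	234	157	120	197	143	112	180	318	283	353	312	308	316	211	208	214
L3'4	86	66	106	NA	NA	NA	NA	NA	NA	166	140	191	150	142	158	102	96	108
L3	73	51	95	78	62	95	72	54	93	112	92	133	122	102	143	83	69	97
M	55	43	67	77	61	93	59	49	70	NA	NA	NA	116	107	124	79	73	85
N	64	50	78	77	61	93	58	51	66	NA	NA	NA	119	115	122	80	78	83
R	60	47	74	NA	NA	NA	NA	NA	NA	NA	NA	NA	128	124	131	86	84	89
P	NA	NA	NA	54	43	66	57	43	71	112	91	133	101	87	115	69	59	78
U5	36	25	47	30	22	37	50	39	62	NA	NA	NA	63	57	70	43	39	47
A2	13	9	18	NA	NA	NA	30	22	40	NA	NA	NA	41	37	44	28	25	30
B2	15	9	20	NA	NA	NA	23	16	31	38	25	50	46	37	55	31	25	37
C1	17	12	26	NA	NA	NA	31	22	41	NA	NA	NA	30	24	37	21	16	25
D1	14	9	18	NA	NA	NA	31	22	40	NA	NA	NA	32	17	47	22	12	32
D4h3a	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	26	22	29	17	15	21
X2a	13	6	20	NA	NA	NA	21	14	30	NA	NA	NA	22	14	31	15	10	21
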