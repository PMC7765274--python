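no	compound	abbrev	lds_1b06	lds_6fpc	ci_printed
1	Difloxacin	DIF	73.21	69.19	1.074
2	Enrofloxacin	ENR	68.72	72.86	1.069
3	Norfloxacin	NOR	64.63	62.14	0.956
4	Lomefloxacin	LOM	64.07	59.99	0.936
5	Levofloxacin	LEV	65.51	71.06	1.032
6	Pefloxacin	PEF	69.37	66.10	1.022
7	Fleroxacin	FLE	63.24	65.18	0.969
8	Ciprofloxacin	CIP	68.95	64.63	1.007
9	Balofloxacin	BAL	49.90	48.84	0.745
10	Marbofloxacin	MAR	66.70	69.40	1.028
11	Pipemidic acid	PIP	69.90	66.52	1.029
12	Cinoxacin	CIN	69.14	69.79	1.049
13	Enoxacin	ENO	67.21	65.650	1.002
14	Danofloxacin	DAN	74.21	74.57	1.123
15	Gatifloxacin	GAT	52.29	51.07	0.780
16	Ofloxacin	OFL	65.51	71.06	1.032
17	Rufloxacin	RUF	59.46	64.04	0.933
18	Pazufloxacin	PAZ	73.50	69.93	1.082
19	Nadifloxacin	NAD	65.95	69.04	1.019
20	Moxifloxacin	MOX	56.09	57.62	0.858
21	Sparfloxacin	SPA	72.78	68.90	1.069
22	Sarafloxacin	SAR	65.93	62.12	0.966
23	Amifloxacin	AMI	68.55	67.45	1.026
24	Besifloxacin	BES	64.10	56.74	0.911
25	Clinafloxacin	CLI	64.58	69.36	1.012
26	Grepafloxacin	GRE	68.90	66.78	1.024
27	Orbifloxacin	ORB	66.90	67.14	1.012
28	Sitafloxacin	SIT	69.50	61.53	0.987
29	Temafloxacin	TEM	72.64	68.20	1.062
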