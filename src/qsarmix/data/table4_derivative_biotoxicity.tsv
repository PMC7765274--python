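parent	id	name	ci_pred	ci_change	lds_1b06	lds_1b06_change	lds_6fpc	lds_6fpc_change
ENR	ENR	ENR	1.069		68.72		72.86
ENR	D-1	19-Fluorine-ENR	0.901	-15.72	85.00	23.69	51.06	-22.93
ENR	D-2	19-Chlorine-ENR	1.035	-3.18	82.61	20.22	77.36	6.17
ENR	D-3	19-Bromine-ENR	1.036	-3.09	88.54	28.84	78.05	7.12
ENR	D-4	9-Methyl-ENR	1.005	-5.99	91.14	32.63	56.67	-22.23
ENR	D-5	9-Aldehyde-ENR	0.861	-19.46	91.92	33.77	67.11	-7.90
ENR	D-6	9-Hydroxy-ENR	1.018	-4.77	89.32	29.98	64.93	-10.89
ENR	D-7	9-Methanol-ENR	0.858	-19.74	92.96	35.28	72.65	-0.30
ENR	D-8	9-Ethyl-ENR	0.903	-15.53	85.76	24.79	64.04	-12.11
ENR	D-9	19-Fluorine-9-Methyl-ENR	1.024	-4.21	88.62	28.96	60.54	-16.91
ENR	D-10	19-Fluorine-9-Aldehyde-ENR	0.876	-18.05	92.03	33.92	70.03	-3.89
ENR	D-11	19-Fluorine-9-Hydroxy-ENR	1.024	-4.21	92.69	34.88	72.17	-0.95
ENR	D-12	19-Fluorine-9-Methanol-ENR	0.878	-17.87	93.43	35.96	68.80	-5.57
ENR	D-13	19-Fluorine-9-Ethyl-ENR	0.923	-13.66	95.77	39.36	61.19	-16.02
ENR	D-14	19-Chlorine-9-Methyl-ENR	0.854	-20.11	88.21	28.37	60.22	-17.35
ENR	D-15	19-Chlorine-9-Aldehyde-ENR	0.955	-10.66	92.81	35.06	63.79	-12.46
ENR	D-16	19-Chlorine-9-Hydroxy-ENR	1.027	-3.93	86.93	26.50	63.16	-13.31
ENR	D-17	19-Chlorine-9-Methanol-ENR	0.873	-18.33	96.94	41.07	70.00	-3.93
ENR	D-18	19-Chlorine-9-Ethyl-ENR	0.899	-15.90	93.06	35.42	55.60	-23.70
ENR	D-19	19-Bromine-9-Methyl-ENR	1.028	-3.84	92.17	34.13	64.85	-11.00
ENR	D-20	19-Bromine-9-Aldehyde-ENR	0.876	-18.05	91.44	33.05	64.85	-11.00
ENR	D-21	19-Bromine-9-Hydroxy-ENR	1.027	-3.93	88.81	29.24	65.76	-9.76
ENR	D-22	19-Bromine-9-Methanol-ENR	0.872	-18.43	92.26	34.26	66.85	-8.26
ENR	D-23	19-Bromine-9-Ethyl-ENR	0.894	-16.37	87.82	27.80	64.09	-12.04
SPA	SPA	SPA	1.069		72.78		68.90
SPA	D-1	17-Fluorine-SPA	1.000	-6.45	96.18	32.15	75.74	9.93
SPA	D-2	17-Chlorine-SPA	1.038	-2.90	99.68	36.95	85.22	23.69
SPA	D-3	17-Bromine-SPA	1.036	-3.09	91.50	25.73	82.42	19.63
SPA	D-4	8-Nitroso-SPA	0.970	-9.26	76.31	4.84	74.43	8.03
SPA	D-5	8-Nitro-SPA	1.014	-5.14	83.25	14.38	72.34	5.00
SPA	D-6	8-NF2-SPA	1.025	-4.12	74.68	2.61	57.64	-16.34
SPA	D-7	8-Aldehyde-SPA	1.032	-3.46	98.72	35.64	78.03	13.26
SPA	D-8	8-Carboxyl-SPA	0.906	-15.25	91.22	25.33	76.17	10.56
SPA	D-9	17-Fluorine-8-Nitroso-SPA	1.013	-5.24	99.80	37.12	68.22	-0.98
SPA	D-10	17-Fluorine-8-Nitro-SPA	0.966	-9.64	83.04	14.09	61.17	-11.21
SPA	D-11	17-Fluorine-8-NF2-SPA	0.965	-9.73	75.12	3.21	62.79	-8.86
SPA	D-12	17-Fluorine-8-Aldehyde-SPA	0.958	-10.38	95.98	31.87	/	/
SPA	D-13	17-Fluorine-8-Carboxyl-SPA	1.024	-4.21	/	/	76.72	11.36
SPA	D-14	17-Chlorine-8-Nitroso-SPA	1.018	-4.77	87.27	19.91	85.60	24.24
SPA	D-15	17-Chlorine-8-Nitro-SPA	1.043	-2.43	69.73	-4.19	55.77	-19.05
SPA	D-16	17-Chlorine-8-NF2-SPA	1.024	-4.21	73.36	0.80	58.68	-14.82
SPA	D-17	17-Chlorine-8-Aldehyde-SPA	1.009	-5.61	77.98	7.14	70.75	2.69
SPA	D-18	17-Chlorine-8-Carboxyl-SPA	0.917	-14.22	/	/	/	/
SPA	D-19	17-Bromine-8-Nitroso-SPA	1.031	-3.55	96.83	33.04	59.26	-13.99
SPA	D-20	17-Bromine-8-Nitro-SPA	1.043	-2.43	72.83	0.07	63.20	-8.26
SPA	D-21	17-Bromine-8-NF2-SPA	1.013	-5.24	73.18	0.55	55.72	-19.13
SPA	D-22	17-Bromine-8-Aldehyde-SPA	1.047	-2.06	95.45	31.14	69.82	1.33
SPA	D-23	17-Bromine-8-Carboxyl-SPA	1.009	-5.61	98.26	35.00	82.88	20.30
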