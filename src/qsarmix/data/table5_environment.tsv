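parent	id	name	logkow	logkow_change	logkoc	logkoc_change	biodeg	biodeg_change	algae_ec50	algae_ec50_change	cyano_lds	cyano_lds_change
ENR	ENR	ENR	0.700		0.207		3.194		989.25		102.61
ENR	D-2	19-Chlorine-ENR	0.460	-34.29	0.074	-64.25	3.090	-3.26	1525.53	54.21	93.48	-8.90
ENR	D-3	19-Bromine-ENR	0.550	-21.43	0.124	-40.10	3.095	-3.10	1477.53	49.36	83.06	-19.05
ENR	D-7	9-Methanol-ENR	-0.420	-160.00	-0.824	-498.07	3.066	-4.01	6073.24	513.93	106.87	4.15
ENR	D-10	19-Fluorine-9-Aldehyde-ENR	-0.330	-147.14	-0.592	-385.99	3.008	-5.82	5337.51	439.55	87.82	-14.42
ENR	D-11	19-Fluorine-9-Hydroxy-ENR	-0.530	-175.71	-0.306	-247.83	3.031	-5.10	7075.86	615.28	87.96	-14.28
ENR	D-12	19-Fluorine-9-Methanol-ENR	-0.970	-238.57	-1.128	-644.93	2.976	-6.83	14757.63	1391.81	103.42	0.78
ENR	D-17	19-Chlorine-9-Methanol-ENR	-0.650	-192.86	-0.951	-559.42	3.033	-5.04	9349.34	845.10	109.27	6.48
SPA	SPA	SPA	1.400		0.995		3.089		356.04		81.62
SPA	D-1	17-Fluorine-SPA	0.850	-39.29	0.691	-30.55	3.113	0.78	864.68	142.86	80.84	-0.94
SPA	D-2	17-Chlorine-SPA	1.160	-17.14	0.863	-13.27	3.084	-0.16	546.64	53.53	76.85	-5.84
SPA	D-3	17-Bromine-SPA	1.250	-10.71	0.912	-8.34	3.052	-1.20	525.12	47.49	84.28	3.26
SPA	D-4	8-Nitroso-SPA	2.180	55.71	1.427	43.42	3.240	4.89	105.17	-70.46	66.40	-18.65
SPA	D-5	8-Nitro-SPA	2.130	52.14	1.640	64.82	2.951	-4.47	118.85	-66.62	65.15	-20.17
SPA	D-7	8-Aldehyde-SPA	2.030	45.00	1.136	14.17	3.081	-0.26	133.87	-62.40	77.32	-5.27
SPA	D-8	8-Carboxyl-SPA	1.090	-22.14	0.845	-15.08	3.031	-1.88	618.44	73.70	77.64	-4.87
SPA	D-14	17-Chlorine-8-Nitroso-SPA	1.950	39.29	1.300	30.65	3.078	-0.36	161.20	-54.72	68.43	-16.15
SPA	D-17	17-Chlorine-8-Aldehyde-SPA	1.790	27.86	1.003	0.80	3.047	-1.36	205.21	-42.36	77.49	-5.05
SPA	D-22	17-Bromine-8-Aldehyde-SPA	1.880	34.29	1.053	5.83	3.045	-1.42	196.55	-44.80	83.50	2.31
SPA	D-23	17-Bromine-8-Carboxyl-SPA	0.950	-32.14	0.768	-22.81	3.046	-1.39	903.20	153.68	84.11	3.06
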