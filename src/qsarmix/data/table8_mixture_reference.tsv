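environment	group	combination	m	m0	mti
farmland	1	A*B	1.624	1.803	0.177
farmland	2	A*C	1.604	1.821	0.212
farmland	3	A*D	1.609	1.817	0.204
farmland	4	B*C	1.781	1.977	0.153
farmland	5	B*D	1.786	1.983	0.152
farmland	6	C*D	1.766	1.994	0.176
farmland	7	A*B*C	2.504	2.780	0.102
farmland	8	A*B*D	2.509	2.785	0.102
farmland	9	A*C*D	2.489	2.811	0.118
farmland	10	B*C*D	2.667	2.960	0.096
farmland	11	A*B*C*D	3.390	3.763	0.079
garden	1	A*B	0.231	1.803	3.486
garden	2	A*C	0.228	1.821	3.464
garden	3	A*D	0.229	1.817	3.470
garden	4	B*C	0.253	1.977	3.013
garden	5	B*D	0.254	1.983	3.001
garden	6	C*D	0.251	1.994	3.001
garden	7	A*B*C	0.356	2.780	2.009
garden	8	A*B*D	0.357	2.785	2.005
garden	9	A*C*D	0.354	2.811	2.004
garden	10	B*C*D	0.379	2.960	1.893
garden	11	A*B*C*D	0.482	3.763	1.550
woodland	1	A*B	0.126	1.803	4.515
woodland	2	A*C	0.124	1.821	4.475
woodland	3	A*D	0.125	1.817	4.485
woodland	4	B*C	0.138	1.977	3.902
woodland	5	B*D	0.139	1.983	3.886
woodland	6	C*D	0.137	1.994	3.879
woodland	7	A*B*C	0.194	2.780	2.602
woodland	8	A*B*D	0.195	2.785	2.597
woodland	9	A*C*D	0.193	2.811	2.591
woodland	10	B*C*D	0.207	2.960	2.451
woodland	11	A*B*C*D	0.263	3.763	2.008
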