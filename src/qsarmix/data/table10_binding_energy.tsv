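environment	group	combination	g_bind_kcal_mol	mti
farmland	1	A*B	-239.51	0.177
farmland	2	A*C	-79.48	0.212
farmland	3	A*D	-143.99	0.204
farmland	4	B*C	-187.77	0.153
farmland	5	B*D	-214.18	0.152
farmland	6	C*D	-68.97	0.176
farmland	7	A*B*C	-230.38	0.102
farmland	8	A*B*D	-317.98	0.102
farmland	9	A*C*D	-154.06	0.118
farmland	10	B*C*D	-171.80	0.096
farmland	11	A*B*C*D	-331.98	0.079
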