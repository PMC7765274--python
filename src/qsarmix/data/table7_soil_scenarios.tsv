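environment	label	compound	concentration_ug_per_kg	biotoxicity
farmland	A	ENR	0.773	1.069
farmland	B	9-Methanol-ENR	0.773	0.858
farmland	C	19-Fluorine-9-Methanol-ENR	0.773	0.878
farmland	D	19-Chlorine-9-Methanol-ENR	0.773	0.873
garden	A	ENR	0.110	1.069
garden	B	9-Methanol-ENR	0.110	0.858
garden	C	19-Fluorine-9-Methanol-ENR	0.110	0.878
garden	D	19-Chlorine-9-Methanol-ENR	0.110	0.873
woodland	A	ENR	0.060	1.069
woodland	B	9-Methanol-ENR	0.060	0.858
woodland	C	19-Fluorine-9-Methanol-ENR	0.060	0.878
woodland	D	19-Chlorine-9-Methanol-ENR	0.060	0.873
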