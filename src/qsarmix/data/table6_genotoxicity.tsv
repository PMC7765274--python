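parent	id	name	ploec	ploec_change
ENR	ENR	ENR	8.839
ENR	D-7	9-Methanol-ENR	8.854	0.17
ENR	D-12	19-Fluorine-9-Methanol-ENR	8.397	-5.00
ENR	D-17	19-Chlorine-9-Methanol-ENR	8.405	-4.91
SPA	SPA	SPA	7.486
SPA	D-1	17-Fluorine-SPA	8.073	7.84
SPA	D-2	17-Chlorine-SPA	7.939	6.05
SPA	D-3	17-Bromine-SPA	8.035	7.33
SPA	D-8	8-Carboxyl-SPA	7.653	2.23
SPA	D-23	17-Bromine-8-Carboxyl-SPA	7.870	5.13
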