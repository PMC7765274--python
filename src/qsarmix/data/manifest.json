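{
 "rules/enr_default.yaml": "d55958f6e9680cfbb113d08044a9d462e86f1060050d52b171972e0e5754cb78",
 "rules/spa_default.yaml": "4d13f1e0bd6803e87b4799468670e3f3927fc157a3a0dd69a27132a76b5b17c0",
 "table10_binding_energy.tsv": "9c55d390a20d696c9c7f29128d5b8808f2b3173cd83ca731609595412324a41a",
 "table2_docking_scores.tsv": "1b2a5158f2be67fcbfacea4b9ff1a19ef8770302f60ef5ff77e1c230a6ca9913",
 "table4_derivative_biotoxicity.tsv": "0ba236143efdcd815bcaf1f9f2ec2ee897301321da0cad8450fab5e4be964943",
 "table5_environment.tsv": "8e8481b7dca8678f782e5d86ec7c09751556cedf0c09b593507b32d915fa707d",
 "table6_genotoxicity.tsv": "d96f6b46ea254d68af19555bea3f5f3b16b693fa6b521b468365d78d80879558",
 "table7_soil_scenarios.tsv": "b56f5144183f3642dfdcb2d84cd9c59c6382ea8faa1d9a09c1a5eebbcf2fce67",
 "table8_mixture_reference.tsv": "bf9e3381a2f17fee1c4edc40326fd3f207c475a036f5abf9ba5c52cbd484faf1"
}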