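nitro	[NX3+](=O)[O-]	aromatic/aliphatic nitro group
azo	[#6]N=N[#6]	azo compound
peroxide	[OX2][OX2]	peroxide
acyl_halide	[CX3](=O)[F,Cl,Br,I]	acyl halide
sulfonyl_halide	S(=O)(=O)[F,Cl,Br,I]	sulfonyl halide
isocyanate	N=C=O	isocyanate
azide	[N-]=[N+]=N	azide
nitroso	[#6][NX2]=O	nitroso group
quinone	O=C1C=CC(=O)C=C1	para-quinone
hydrazine	[NX3;!$(N=*)][NX3;!$(N=*)]	hydrazine
thiol	[#6][SX2H]	free thiol
anhydride	[CX3](=O)O[CX3](=O)	acid anhydride
dicarbonyl_1_2	[CX3](=O)[CX3](=O)	1,2-dicarbonyl
aliphatic_long_chain	[CH2][CH2][CH2][CH2][CH2][CH2][CH2][CH2]	8+ unbranched methylenes
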