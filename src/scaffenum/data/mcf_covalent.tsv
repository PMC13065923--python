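acrylamide	C=C[CX3](=O)[NX3]	acrylamide Michael acceptor
vinyl_sulfone	C=CS(=O)(=O)	vinyl sulfone Michael acceptor
acrylate	C=C[CX3](=O)O	acrylate ester Michael acceptor
alpha_halo_ketone	[CX3](=O)[CH2][Cl,Br,I]	alpha-halo ketone
aldehyde	[CX3H1]=O	aldehyde
epoxide	C1OC1	epoxide
aziridine	C1NC1	aziridine
isothiocyanate	N=C=S	isothiocyanate
maleimide	O=C1C=CC(=O)N1	maleimide
chloroacetamide	[NX3][CX3](=O)[CH2]Cl	chloroacetamide warhead
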