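*[H]
*C
*F
*Cl
*OC
*C#N
*C(F)(F)F
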