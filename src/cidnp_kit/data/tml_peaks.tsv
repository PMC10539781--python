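species	nucleus	shift_ppm	rel_intensity	significant
TML-	H(6a)	2.06	-1.0	true
TML-	H(8a)	3.09	-0.439	true
TMLH	H(8a)	3.91	0.473	true
TMLH	H(6a)	2.52	0.0	false
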