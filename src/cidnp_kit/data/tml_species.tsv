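species	nucleus	Aiso_MHz
TMLHred	H(6a)	-5.31
TMLHred	H(8a)	15.21
TMLH2red(H5)	H(6a)	1.57
TMLH2red(H5)	H(8a)	18.9
TMLH2red(H1)	H(6a)	-5.38
TMLH2red(H1)	H(8a)	14.41
TMLox	H(6a)	14.93
TMLox	H(8a)	6.42
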