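name	sequence	orientation	gene
cutC_F	TTYGCIGGITAYCARCCNTT	forward	cutC
cutC_R	GNGGYTCIACRCAICCCAT	reverse	cutC
cntA_F	TAYCAYGCITGGRCITTYAARCT	forward	cntA
cntA_R	RCAGTGRTARCAYTCSAKRTAGTTRTCRAC	reverse	cntA
16S_F	AGRGTTHGATYMTGGCTCAG	forward	16S
16S_R	TGCTGCCTCCCGTAGGAGT	reverse	16S
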