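dusp	inducers	substrates	provenance
DUSP1	ERK,p38	JNK	known
DUSP2	ERK,JNK	ERK,p38	known
DUSP3	UNKNOWN	ERK,JNK,p38	predicted
DUSP4	ERK	ERK,JNK	known
DUSP5	ERK	ERK	known
DUSP9	UNKNOWN	ERK	predicted
DUSP16	UNKNOWN	JNK,p38	predicted
DUSP23	UNKNOWN	ERK,JNK,p38	predicted
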