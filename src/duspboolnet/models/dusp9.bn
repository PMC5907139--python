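# inducer set is a model prediction (regulation only partially known)
#input: Herceptin Basal
HER2* = not Herceptin
ERK* = (HER2 or Basal) and not DUSP9
JNK* = HER2
p38* = HER2
DUSP9* = JNK
Survival* = not (JNK and p38)
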