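#input: Herceptin Basal
HER2* = not Herceptin
ERK* = (HER2 or Basal) and not DUSP2
JNK* = HER2
p38* = (HER2 or Basal) and not DUSP2
DUSP2* = ERK or JNK
Survival* = not (JNK and p38)
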