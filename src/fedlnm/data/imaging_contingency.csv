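group,tp,fp,fn,tn
CT,31,27,64,317
MRI,28,24,50,338
PET/CT,45,45,33,270
C-M,27,25,45,239
C-P,42,49,29,188
M-P,33,43,27,189
C-M-P,31,40,24,135
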