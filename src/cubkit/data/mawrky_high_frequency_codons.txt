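AGG
AGA
CUC
CUG
UUG
AGC
UCC
UCG
GUG
GUC
ACC
ACG
GGC
GCC
GCU
CCG
CCA
UGC
AAG
UUC
AAC
GAG
UAC
CAG
CAC
GAU
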