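source,target
U,1
X,1
1,K
A1,2
A2,2
A3,2
A4,2
2,K
K,3
S,3
3,T
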