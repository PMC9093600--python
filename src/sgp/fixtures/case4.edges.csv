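source,target
U11,1
U12,1
1,K
U21,2
U22,2
2,K
U31,3
U32,3
3,K
U41,4
U42,4
4,K
U51,5
U52,5
5,K
C1,6
C2,6
6,K
V,7
7,P
K,8
P,8
8,M
K,9
Z,9
9,M
M,10
Y,10
10,T
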