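source,target
A,1
B,1
C,1
D,1
1,E
E,2
F,2
G,2
2,J
H,3
I,3
3,F
J,4
M,4
4,P
A,5
J,5
K,5
L,5
5,M
M,6
N,6
O,6
6,A
P,7
7,T
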