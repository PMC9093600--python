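source,target
A,1
B,1
1,E
C,2
D,2
2,J
E,3
H,3
3,I
E,4
F,4
4,K
G,5
I,5
5,M
I,6
J,6
6,N
K,7
O,7
7,T
L,8
M,8
8,O
L,9
N,9
9,T
J,10
10,O
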