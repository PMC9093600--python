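source,target
2,A
3,A
A,1
4,B
5,B
B,1
6,C
7,C
C,2
3,D
8,D
D,4
3,E
9,E
E,4
3,F
10,F
F,4
11,G
12,G
G,4
3,H
H,4
6,I
I,5
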