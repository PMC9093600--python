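id,node_type,label,is_starting_material,is_target,mw
A,substance,A,true,false,
B,substance,B,true,false,
C,substance,C,true,false,
D,substance,D,true,false,
F,substance,F,true,false,
G,substance,G,true,false,
H,substance,H,true,false,
L,substance,L,true,false,
E,substance,E,false,false,
I,substance,I,false,false,
J,substance,J,false,false,
K,substance,K,false,false,
M,substance,M,false,false,
N,substance,N,false,false,
O,substance,O,false,false,
T,substance,T,false,true,
1,reaction,1,,,
2,reaction,2,,,
3,reaction,3,,,
4,reaction,4,,,
5,reaction,5,,,
6,reaction,6,,,
7,reaction,7,,,
8,reaction,8,,,
9,reaction,9,,,
10,reaction,10,,,
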