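id,node_type,label,is_starting_material,is_target,mw
A,substance,A,false,false,
E,substance,E,true,false,
F,substance,F,false,false,
J,substance,J,true,false,
M,substance,M,true,false,
P,substance,P,false,false,
T,substance,T,false,true,
B,substance,B,true,false,
C,substance,C,true,false,
D,substance,D,true,false,
G,substance,G,true,false,
H,substance,H,true,false,
I,substance,I,true,false,
K,substance,K,true,false,
L,substance,L,true,false,
N,substance,N,true,false,
O,substance,O,true,false,
1,reaction,1,,,
2,reaction,2,,,
3,reaction,3,,,
4,reaction,4,,,
5,reaction,5,,,
6,reaction,6,,,
7,reaction,7,,,
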