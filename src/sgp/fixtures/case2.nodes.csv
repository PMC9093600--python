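id,node_type,label,is_starting_material,is_target,mw
U11,substance,U11,true,false,
U12,substance,U12,true,false,
U21,substance,U21,true,false,
U22,substance,U22,true,false,
U31,substance,U31,true,false,
U32,substance,U32,true,false,
U41,substance,U41,true,false,
U42,substance,U42,true,false,
U51,substance,U51,true,false,
U52,substance,U52,true,false,
C1,substance,C1,true,false,
C2,substance,C2,true,false,
V,substance,V,true,false,
Y,substance,Y,true,false,
Z,substance,Z,true,false,
K,substance,K,false,false,
P,substance,P,false,false,
M,substance,M,false,false,
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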