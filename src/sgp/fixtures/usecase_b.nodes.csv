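id,node_type,label,is_starting_material,is_target,mw
1,substance,1,false,true,
2,substance,2,false,false,
4,substance,4,false,false,
5,substance,5,true,false,
3,substance,3,true,false,
6,substance,6,true,false,
7,substance,7,true,false,
8,substance,8,true,false,
9,substance,9,true,false,
10,substance,10,true,false,
11,substance,11,true,false,
12,substance,12,true,false,
A,reaction,A,,,
B,reaction,B,,,
C,reaction,C,,,
D,reaction,D,,,
E,reaction,E,,,
F,reaction,F,,,
G,reaction,G,,,
H,reaction,H,,,
I,reaction,I,,,
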