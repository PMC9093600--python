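id,node_type,label,is_starting_material,is_target,mw
U,substance,U,true,false,
X,substance,X,true,false,
A1,substance,A1,true,false,
A2,substance,A2,true,false,
A3,substance,A3,true,false,
A4,substance,A4,true,false,
S,substance,S,true,false,
K,substance,K,false,false,
T,substance,T,false,true,
1,reaction,1,,,
2,reaction,2,,,
3,reaction,3,,,
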