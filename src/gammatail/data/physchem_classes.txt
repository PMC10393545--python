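# Physicochemical partition of the 20 amino acids, used when picking
# class-preserving (C2-style) control substitutions.
hydrophobic=A,I,L,M,V
aromatic=F,W,Y
polar=N,Q,S,T
positive=H,K,R
negative=D,E
special=C,G,P
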