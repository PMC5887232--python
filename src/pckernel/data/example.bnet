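# Seven-node example network (phenotype node P).
# Rules for P, C, E and A are stated in the accompanying text; B and D were
# transcribed from the published network figure: B* = C&(!F) is the unique
# rule whose only forcing solution for B = 1 is {(C,F) = (1,0)}, D* = A puts
# A alone in the 3rd layer, and F is a rule-less input node, which makes
# {F = 0} a leaf in the last tree level. The transcription is confirmed by
# the published state-space fixed points (A,B,C,D,E,F,P) = (1,0,1,1,1,1,1)
# and (0,0,0,0,0,0,0), both fixed under these rules.
A, F
B, C&(!F)
C, (!B)&D&E
D, A
E, D|F
P, C&E
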