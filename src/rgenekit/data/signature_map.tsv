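signature	label
PF00931	NB-ARC
IPR002182	NB-ARC
PF01582	TIR
IPR000157	TIR
PF05659	RPW8
IPR008808	RPW8
PF00560	LRR
PF07725	LRR
PF12799	LRR
PF13306	LRR
PF13855	LRR
IPR032675	LRR
Coil	CC
COILS	CC
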