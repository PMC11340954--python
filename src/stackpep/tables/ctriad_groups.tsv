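group	residues
g1	AGV
g2	ILFP
g3	YMTS
g4	HNQW
g5	RK
g6	DE
g7	C
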