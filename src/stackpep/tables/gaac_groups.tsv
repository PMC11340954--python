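group	residues	description
g1	GAVLMI	aliphatic
g2	FYW	aromatic
g3	KRH	positive charge
g4	DE	negative charge
g5	STCPNQ	uncharged
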