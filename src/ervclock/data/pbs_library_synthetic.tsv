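trna	pbs	note
K	TGGCGCCCAACGTGGGGC	synthetic lysine-tRNA primer binding site (default template PBS)
R	TGGTACCAGGTTCGAAAC	synthetic arginine decoy
W	TGACCCCGTCGTGGGGAA	synthetic tryptophan decoy
G	TGGTGCGTCAATTCCAGC	synthetic glycine decoy
H	TGGGATACTCGCAATGGA	synthetic histidine decoy
F	TGGCAAGTTCAGCCTGGT	synthetic phenylalanine decoy
L	TGGTAGAGCGCTCGCTTA	synthetic leucine decoy
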