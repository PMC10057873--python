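peptide	score	binding_energy	interactions
IVPQH	-170.40	-1.87	CYS285
PIVF	-188.22	-2.18	SER289;CYS285
IIQGR	-170.12	-2.07	ARG288
QPY	-168.94	-5.61	CYS285;SER289;TYR473
QSPVF	-175.73	-6.38	CYS285;GLY284
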