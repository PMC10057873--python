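peptide	logp
IVPQH	2.25
PIVF	2.36
IIQGR	1.28
QPY	1.34
QSPVF	2.32
GW9662	1.81
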