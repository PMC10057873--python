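# Hydrolyzed fractions of rice prolamin (BIOPEP UWM 1153) after simulated
# pepsin/trypsin/chymotrypsin digestion; one fragment per line, in order.
# Concatenating the fragments restores the parent sequence.
M
K
IIF
F
F
AL
L
AEAACSASAQF
DAVTQVY
R
QY
QL
QQQM
L
SPCGEF
VR
QQCSTVATPF
F
QSPVF
QL
R
N
CQVM
QQQCCQQL
R
M
IAQQSH
CQAISSVQAIVQQL
QL
QQF
SGVY
F
DQAQAQAQAM
L
GL
N
L
PSICGIY
PSY
N
TVPEIPTVGGIW
Y
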