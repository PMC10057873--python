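# Hydrolyzed fractions of rice glutelin (BIOPEP UWM 1536) after simulated
# pepsin/trypsin/chymotrypsin digestion; one fragment per line, in order.
# Concatenating the fragments restores the parent sequence.
M
ASIN
R
PIVF
F
TVCL
F
L
L
CDGSL
AQQL
L
GQSTSQW
QSSR
R
GSPR
GCR
F
DR
L
QAF
EPIR
SVR
SQAGTTEF
F
DVSN
EL
F
QCTGVSVVR
R
VIEPR
GL
L
L
PH
Y
TN
GASL
VY
IIQGR
GITGPTF
PGCPETY
QQQF
QQSGQAQL
TESQSQSH
K
F
K
DEH
QK
IH
R
F
R
QGDVIAL
PAGVAH
W
CY
N
DGEVPVVAIY
VTDIN
N
GAN
QL
DPR
QR
DF
L
L
AGN
K
R
N
PQAY
R
R
EVEEW
SQN
IF
SGF
STEL
L
SEAF
GISN
QVAR
QL
QCQN
DQR
GEIVR
VER
GL
SL
L
QPY
ASL
QEQEQGQM
QSR
EH
Y
QEGGY
QQSQY
GSGCPN
GL
DETF
CTM
R
VR
QN
IDN
PN
R
ADTY
N
PR
AGR
VTN
L
N
SQN
F
PIL
N
L
VQM
SAVK
VN
L
Y
QN
AL
L
SPF
W
N
IN
AH
SIVY
ITQGR
AQVQVVN
N
N
GK
TVF
N
GEL
R
R
GQL
L
IVPQH
Y
VVVK
K
AQR
EGCAY
IAF
K
TN
PN
SM
VSH
IAGK
SSIF
R
AL
PTDVL
AN
AY
R
ISR
EEAQR
L
K
H
N
R
GDEF
GAF
TPL
QY
K
SY
QDVY
N
VAESS
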