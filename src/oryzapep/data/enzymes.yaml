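# Default gastrointestinal protease rule set.
# P1 specificity: cleavage occurs C-terminal to any residue in cut_after,
# unless the following residue (P1') is in not_before.
# The per-enzyme attribution of {M, N, H} follows BIOPEP-style conventions;
# the simulation unions all cut sites (simultaneous digestion), so only the
# combined set {F,L,W,Y,M,K,R,N,H} is load-bearing.
enzymes:
  - name: pepsin (pH 1.3)
    ec: 3.4.23.1
    cut_after: [F, L]
    not_before: []
  - name: trypsin
    ec: 3.4.21.4
    cut_after: [K, R]
    not_before: []
  - name: chymotrypsin
    ec: 3.4.21.1
    cut_after: [W, Y, F, M, L, N, H]
    not_before: []
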