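trinucleotide	weight
ACA	0.86
ACC	1.08
ACG	1.31
ACT	0.94
CCA	1.02
CCC	1.17
CCG	1.38
CCT	1.05
GCA	1.01
GCC	1.21
GCG	1.42
GCT	1.07
TCA	0.88
TCC	1.04
TCG	1.27
TCT	0.91
ATA	0.72
ATC	0.95
ATG	0.89
ATT	0.74
CTA	0.84
CTC	1.06
CTG	1.12
CTT	0.90
GTA	0.82
GTC	1.03
GTG	1.09
GTT	0.85
TTA	0.70
TTC	0.92
TTG	0.87
TTT	0.68
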