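residue	value
# Synthetic stand-in antimicrobial propensity index (lower = more
# antimicrobial). The ordering follows the qualitative structure of
# IC50-derived propensity scales (cationic < aromatic/cysteine <
# aliphatic < polar < acidic); the numeric values are NOT a published
# scale. Replace this file with a reference scale for production runs.
R	0.08
K	0.10
W	0.12
C	0.14
F	0.15
Y	0.16
H	0.18
I	0.20
V	0.21
L	0.22
M	0.24
G	0.26
A	0.28
T	0.32
S	0.34
N	0.38
Q	0.40
P	0.45
E	0.55
D	0.60
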