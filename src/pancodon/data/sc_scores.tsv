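aa	score
# Size/complexity (S/C) cost scores per amino acid (Dufton-style scale).
# Anchored entries: G 1, A 4.8, I 16.0, S 17.8, K 30.1, D 32.7, N 33.7,
# E 36.5, F 44.0, R 56.3, Y 57.0, C 57.2.
# The remaining entries (V, L, T, P, Q, M, H, W) are SYNTHETIC estimates
# chosen to respect the high-S/C membership set {C,F,H,M,R,W,Y} (>40);
# override with --sc-table if the full published table is available.
G	1
A	4.8
V	13.0
I	16.0
L	16.5
S	17.8
T	21.0
P	22.5
K	30.1
D	32.7
N	33.7
Q	35.0
E	36.5
F	44.0
M	43.5
H	49.0
R	56.3
Y	57.0
C	57.2
W	73.0
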