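# Solvent-accessible surface area in the unfolded tripeptide state
# (Rose et al. 1985 family, normalized units as tabulated in the
# auto-covariance PPI descriptor literature).
A 1.181
C 1.461
D 1.587
E 1.862
F 2.228
G 0.881
H 2.025
I 1.810
K 2.258
L 1.931
M 2.034
N 1.655
P 1.468
Q 1.932
R 2.560
S 1.298
T 1.525
V 1.645
W 2.663
Y 2.368
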