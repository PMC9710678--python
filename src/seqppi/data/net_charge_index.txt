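# Net charge index of side chains (Zhou et al. / Klein et al. tabulation used
# in auto-covariance PPI descriptor studies).
A 0.007187
C -0.036610
D -0.023820
E 0.006802
F 0.037552
G 0.179052
H -0.010690
I 0.021631
K 0.017708
L 0.051672
M 0.002683
N 0.005392
P 0.239531
Q 0.049211
R 0.043587
S 0.004627
T 0.003352
V 0.057004
W 0.037977
Y 0.023599
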