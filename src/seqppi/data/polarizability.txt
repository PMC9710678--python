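# Polarizability parameter (Charton & Charton 1982; AAindex CHAM820101).
A 0.046
C 0.128
D 0.105
E 0.151
F 0.290
G 0.000
H 0.230
I 0.186
K 0.219
L 0.186
M 0.221
N 0.134
P 0.131
Q 0.180
R 0.291
S 0.062
T 0.108
V 0.140
W 0.409
Y 0.298
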