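# Volume of side chains (Krigbaum & Komoriya 1979 family; cf. AAindex KRIW790103).
A 27.5
C 44.6
D 40.0
E 62.0
F 115.5
G 0.0
H 79.0
I 93.5
K 100.0
L 93.5
M 94.1
N 58.7
P 41.9
Q 80.7
R 105.0
S 29.3
T 51.3
V 71.5
W 145.5
Y 117.3
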