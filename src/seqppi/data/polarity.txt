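# Polarity (Grantham 1974; AAindex GRAR740102).
A 8.1
C 5.5
D 13.0
E 12.3
F 5.2
G 9.0
H 10.4
I 5.2
K 11.3
L 4.9
M 5.7
N 11.6
P 8.0
Q 10.5
R 10.5
S 9.2
T 8.6
V 5.9
W 5.4
Y 6.2
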