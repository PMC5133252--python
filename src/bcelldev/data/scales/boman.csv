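residue,value
A,-1.81
R,14.92
N,6.64
D,8.72
C,-1.28
Q,5.54
E,6.81
G,-0.94
H,4.66
I,-4.92
L,-4.92
K,5.55
M,-2.35
F,-2.98
P,0.0
S,3.40
T,2.57
W,-2.33
Y,-0.14
V,-4.04
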