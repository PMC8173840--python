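residue	percent
F	3.90
H	0.00
I	4.60
K	0.00
L	7.00
M	0.00
R	4.50
T	4.70
V	7.40
W	0.00
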