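residue	columba_livia_pct	gallus_gallus_pct
F	2.60	3.00
H	0.70	0.60
I	4.60	4.50
K	0.30	0.20
L	6.30	6.60
M	1.20	1.20
R	3.50	4.60
T	5.10	5.10
V	8.90	7.90
W	0.30	0.20
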