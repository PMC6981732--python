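residue	fraction
A	0.0810
C	0.0160
D	0.0580
E	0.0620
F	0.0400
G	0.0750
H	0.0230
I	0.0560
K	0.0590
L	0.0870
M	0.0210
N	0.0450
P	0.0450
Q	0.0370
R	0.0480
S	0.0590
T	0.0580
V	0.0710
W	0.0150
Y	0.0370
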