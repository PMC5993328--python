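aa	name	logP	pI
A	Ala	-3.0	6.00
R	Arg	-4.2	10.76
N	Asn	-3.8	5.41
D	Asp	-2.8	2.77
C	Cys	-2.5	5.07
Q	Gln	-3.6	5.65
E	Glu	-3.7	3.22
G	Gly	-3.2	5.97
H	His	-3.3	7.59
I	Ile	-1.7	6.02
L	Leu	-1.5	5.98
K	Lys	-3.0	9.74
M	Met	-1.9	5.74
F	Phe	-1.5	5.48
P	Pro	-2.5	6.30
S	Ser	-3.1	5.68
T	Thr	-2.9	5.60
W	Trp	-1.1	5.89
Y	Tyr	-2.3	5.66
V	Val	-2.3	5.96
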