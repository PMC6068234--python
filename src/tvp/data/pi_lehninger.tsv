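# Isoelectric points of the free amino acids (Lehninger, Principles of
# Biochemistry, standard table). One-letter code, pI.
aa	pi
A	6.01
R	10.76
N	5.41
D	2.77
C	5.07
Q	5.65
E	3.22
G	5.97
H	7.59
I	6.02
L	5.98
K	9.74
M	5.74
F	5.48
P	6.48
S	5.68
T	5.87
W	5.89
Y	5.66
V	5.97
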