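# Average (isotope-abundance-weighted) masses of the free amino acids, Da.
# Peptide MW = sum(residue masses) - (N-1) * water mass (one water lost per
# peptide bond). Water (average) = 18.0153 Da.
# residue	mass_da
A	89.0941
C	121.1541
D	133.1039
E	147.1308
F	165.1919
G	75.0672
H	155.1564
I	131.1747
K	146.1894
L	131.1747
M	149.2079
N	132.1191
P	115.1320
Q	146.1460
R	174.2028
S	105.0935
T	119.1204
V	117.1479
W	204.2285
Y	181.1913
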