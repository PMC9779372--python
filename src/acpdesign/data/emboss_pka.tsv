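# EMBOSS pKa set for ionizable groups. Keys: one-letter residue codes for
# side chains plus the special keys NTERM and CTERM for free termini.
# group	pka
C	8.5
D	3.9
E	4.1
H	6.5
K	10.8
R	12.5
Y	10.1
NTERM	8.6
CTERM	3.6
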