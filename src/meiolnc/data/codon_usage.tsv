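# built-in biased codon usage (plant-like A/T third-position preference)
codon	amino_acid	weight
GCA	A	0.294118
GCC	A	0.147059
GCG	A	0.117647
GCT	A	0.441176
TGC	C	0.250000
TGT	C	0.750000
GAC	D	0.250000
GAT	D	0.750000
GAA	E	0.714286
GAG	E	0.285714
TTC	F	0.250000
TTT	F	0.750000
GGA	G	0.294118
GGC	G	0.147059
GGG	G	0.117647
GGT	G	0.441176
CAC	H	0.250000
CAT	H	0.750000
ATA	I	0.333333
ATC	I	0.166667
ATT	I	0.500000
AAA	K	0.714286
AAG	K	0.285714
CTA	L	0.208333
CTC	L	0.104167
CTG	L	0.083333
CTT	L	0.312500
TTA	L	0.208333
TTG	L	0.083333
ATG	M	1.000000
AAC	N	0.250000
AAT	N	0.750000
CCA	P	0.294118
CCC	P	0.147059
CCG	P	0.117647
CCT	P	0.441176
CAA	Q	0.714286
CAG	Q	0.285714
AGA	R	0.208333
AGG	R	0.083333
CGA	R	0.208333
CGC	R	0.104167
CGG	R	0.083333
CGT	R	0.312500
AGC	S	0.092593
AGT	S	0.277778
TCA	S	0.185185
TCC	S	0.092593
TCG	S	0.074074
TCT	S	0.277778
ACA	T	0.294118
ACC	T	0.147059
ACG	T	0.117647
ACT	T	0.441176
GTA	V	0.294118
GTC	V	0.147059
GTG	V	0.117647
GTT	V	0.441176
TGG	W	1.000000
TAC	Y	0.250000
TAT	Y	0.750000
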