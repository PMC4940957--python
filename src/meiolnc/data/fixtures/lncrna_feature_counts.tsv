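# Reference cross-tabulation counts: lncRNA feature x DE status by stratum
# (sunflower meiocyte survey scale). Percentages are always recomputed from
# these counts, never stored.
stratum	feature	not_de	de
all	genome_hit	8925	9024
all	three_genotypes	8250	7421
all	three_genotypes_and_genome_hit	8083	7227
all	srna_similarity	3035	3800
all	contains_transposons	831	928
all	total	12006	13321
meiocyte_exclusive	genome_hit	2605	3406
meiocyte_exclusive	three_genotypes	1564	1334
meiocyte_exclusive	three_genotypes_and_genome_hit	1520	1298
meiocyte_exclusive	srna_similarity	1081	1454
meiocyte_exclusive	contains_transposons	279	288
meiocyte_exclusive	total	2881	4014
shared	genome_hit	6320	5618
shared	three_genotypes	6686	6087
shared	three_genotypes_and_genome_hit	6563	5929
shared	srna_similarity	1954	2346
shared	contains_transposons	552	640
shared	total	9125	9307
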