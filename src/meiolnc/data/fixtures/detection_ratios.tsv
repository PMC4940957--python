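# Reference numerator/denominator pairs for printed detection shares.
name	numerator	denominator
lncrna_with_genome_hit_all_three_genotypes	18128	23960
lncrna_without_genome_hit_all_three_genotypes	441	1367
lncrna_with_genome_hit_f1_and_wild	2644	23960
lncrna_without_genome_hit_f1_and_wild	733	1367
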