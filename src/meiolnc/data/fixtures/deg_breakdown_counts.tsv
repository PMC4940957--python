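# Reference gene accounting for the DEG coding-class tree
# (domesticated vs wild meiocyte comparison, sunflower survey scale).
quantity	count
total_genes	59085
deg	29469
noncoding_de	18767
lncrna_de	13321
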