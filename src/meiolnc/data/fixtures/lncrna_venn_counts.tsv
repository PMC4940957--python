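# Reference 3-genotype detection Venn for all identified lncRNAs.
region	count
domesticated	2
wild	0
F1	317
domesticated&wild	0
domesticated&F1	3062
wild&F1	3377
domesticated&wild&F1	18569
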