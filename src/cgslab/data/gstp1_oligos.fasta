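>Model_GST_SEQ_5CG GSTP1-promoter oligo, 5 CpG sites, sense strand
CCCCTGCGATGTCCCGTGGCCCGAGGCCTCGCAGCACGTTGCCTG
>Model_GST_SEQ_2CG GSTP1-promoter oligo, 2 CpG sites, sense strand
CCCCTGCGATGTCCCTGGGCCCAGGGCCCTGCAGCACGTTGCCTG
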