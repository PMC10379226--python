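gene	forward_primer	reverse_primer
SASH1	GAATCCTGACCATGTCCATCCC	AATATGCAGCCTCACAGTGACC
DNAJB4	AGTGAGAATGATGTTTTGAAGCA	AGGGTAAACTTTATGGCATGTAA
GAPDH	GAAATCCCATCACCATCTTCCAGG	GAGCCCCAGCCTTCTCCATG
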