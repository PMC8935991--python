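# Expected filter verdicts for toy.vcf under default FilterConfig, two-bulk mode.
# Hand-derived, record by record:
#  1000: parent hom-ref depth 20, MQ 60, biallelic SNP, bulk depths 18/20 in
#        [8,250], indices 1.0000/0.4000 (not both < 0.3) -> keep
#  2000: parent genotype ./. and depth 0 -> MISSING_PARENT
#  3000: parent 0/1 carries both alleles -> PARENT_HET
#  4000: two ALT alleles -> MULTIALLELIC (index rules skipped for multiallelic)
#  5000: REF A / ALT AT is an insertion -> INDEL
#  6000: MQ 20 < 40 -> LOW_MQ; bulk1 depth 300 > 250 -> HIGH_DEPTH
#  7000: pooled strand table ref (10F,10R) alt (40F,0R), Fisher two-sided
#        Phred 56.1 > 40 -> STRAND_BIAS
#  8000: bulk1 depth 4 < 8 -> LOW_DEPTH
#  9000: indices 0.1000/1.0000; bulk2 >= 0.3 so the low-index rule does not
#        fire -> keep
# 10000: indices 0.1000/0.2000, both < 0.3 -> LOW_INDEX_BOTH_BULKS
# kept count: 2
POS	KEEP	REASONS
1000	1	.
2000	0	MISSING_PARENT
3000	0	PARENT_HET
4000	0	MULTIALLELIC
5000	0	INDEL
6000	0	LOW_MQ,HIGH_DEPTH
7000	0	STRAND_BIAS
8000	0	LOW_DEPTH
9000	1	.
10000	0	LOW_INDEX_BOTH_BULKS
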