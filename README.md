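# bsascan

Bulked-segregant analysis (BSA) from a multi-sample VCF: SNP-index and
ΔSNP-index statistics, simulation-based confidence intervals under the
no-linkage null, sliding-window genome scans, candidate calling, and plots
— plus a synthetic biparental-cross generator so every stage is testable
without real sequencing data.

## Who this is for

Geneticists mapping a trait locus by pooled sequencing of selected progeny
from a biparental cross. Two designs are supported:

* **One-bulk (mutant mapping).** Whole-genome sequence of the parental
  line plus one bulk of F2 progeny selected for a recessive mutant
  phenotype. At a locus unlinked to the trait the bulk carries parental
  and non-parental alleles at ~50:50; at the causal locus the selected
  bulk is fixed for the mutant allele.
* **Two-bulk (QTL mapping).** One parent plus two bulks selected for
  opposite phenotype extremes (e.g. resistant vs susceptible). Trait loci
  fix in opposite directions in the two bulks; everywhere else the bulks
  look alike.

## The statistics

For a bulk with polarized allele depths (AD) at a site,

```
SNP-index  = alt_depth / (ref_depth + alt_depth)
ΔSNP-index = SNP-index(bulk1) − SNP-index(bulk2)
```

where "alt" is the allele absent from the homozygous parent. Under no
linkage, E[SNP-index] = 0.5 and E[Δ] = 0. Significance is assessed without
any distributional assumption: the null is simulated directly by drawing
each bulk's composition from F_k Mendelian segregation (per-individual
heterozygosity 0.5^(k−1)) and read counts binomially at the site's own
depth, giving per-depth empirical confidence intervals. This handles the
strong depth heterogeneity among SNPs that a single analytic band cannot.
An optional Šidák multiple-testing correction uses the chromosome count,
genome size and total map length to set an effective number of tests.

## Worked example

Generate a synthetic one-bulk experiment (two 10-Mb chromosomes, causal
locus at chr1:5,000,000, bulk of 20 F2 individuals, depth 100, 2001
markers) and analyse it:

```
$ bsascan synth --mode one-bulk --seed 11 --out-vcf bulk.vcf --out-truth truth.tsv
wrote bulk.vcf and truth.tsv (seed=11)

$ bsascan onebulk --vcf bulk.vcf --parent PARENT --bulk BULK1 -n 20 --seed 11 --out results
filter summary: total=2001 kept=2001
outputs written to results

$ head -3 results/snp_index.tsv
CHROM  POS    REF  ALT  BULK1_DEPTH  BULK1_SNP_INDEX  CI0.95_LOWER  CI0.95_UPPER  SIG0.95  CI0.99_LOWER  CI0.99_UPPER  SIG0.99
chr1   21514  A    T    100          0.7700           0.3200        0.6800        1        0.2700        0.7400        1
chr1   29836  A    C    100          0.8300           0.3200        0.6800        1        0.2700        0.7400        1
```

Each row reports the fraction of bulk reads carrying the non-parental
allele and the simulated null interval at that site's depth: at depth 100
with 20 F2 individuals the 95% null band is [0.32, 0.68], so an index of
0.77 is flagged (`SIG0.95 = 1`). The top-scoring 2-Mb window is
chr1:4,100,001–6,100,000 with mean SNP-index 0.9816 — the planted causal
locus sits at its center — and `results/candidates.tsv` lists the 1044
flagged markers, all on the linked arm of chr1. `results/scan.png` shows
the per-chromosome scan with window means and shaded 95/99% bands.

For a two-bulk RIL population (20 F6 lines per bulk, as in a typical
QTL-seq design) the call is:

```
bsascan twobulk --vcf calls.vcf --parent P --bulk1 HIGH --bulk2 LOW -n1 20 -n2 20 -F 6 --out results
```

Real inputs are any VCF 4.x with per-sample GT and AD (e.g. from
`bcftools mpileup`+`call`); see `docs/methods.md` for the model, the
filtering rules, and every tunable parameter.

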