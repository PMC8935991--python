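# Methods

## Model and procedure

A biparental cross between a homozygous parent P and a donor of the
non-parental allele produces F1 heterozygotes; selfing to generation F_k
gives individuals whose per-locus genotype at any locus unlinked to a
selected trait follows

    P(het)        = 0.5^(k-1)
    P(hom P)      = P(hom non-P) = (1 - 0.5^(k-1)) / 2

(F2: 1/4, 1/2, 1/4; recombinant inbred lines approach 1/2, 0, 1/2). A bulk
of n such individuals pools 2n chromosomes; sequencing the pool at depth d
at a site yields an observed SNP-index

    SNP-index = alt reads / total reads,

where the counted ("alt") allele is always the one the parent does not
carry. The analysis pipeline is: parse the VCF → polarize against the
parent → filter → per-variant SNP-index (and ΔSNP-index for two bulks) →
sliding-window means → per-depth null confidence intervals by Monte-Carlo
simulation → significance flags, candidate table, plots.

### Polarization

The parent's genotype orients every site: a parent called homozygous for
the first alternate allele has its ref/alt depths swapped before index
computation, so the index is directional (non-parental allele fraction)
and comparable across sites. Sites with a missing or heterozygous parent
cannot be polarized and are filtered.

### The null simulation

Under "no linkage", a bulk's allele frequency p is the pooled frequency of
n independent F_k genotype draws, and reads are Binomial(d, p) given p.
Each replicate of the null statistic draws p fresh and then the reads; the
two-bulk statistic subtracts two independent such draws, each at its own
bulk's depth. No distributional form is assumed for the index itself — the
empirical (1−L)/2 and 1−(1−L)/2 quantiles of the replicates are the
two-sided bounds at confidence level L. Binomial read sampling conditional
on the simulated bulk composition is the canonical generative reading of
"simulate the bulk, then sequence it"; it ignores mapping/calling error,
which the filters are meant to remove upstream.

Bounds are computed per depth because depth varies strongly among sites
and the read-sampling variance term scales as 1/d. The pipeline builds the
table over the *unique observed* depth keys — `(d,)` per variant in
one-bulk mode, the exact `(d1, d2)` pair in two-bulk mode — rather than
over a full integer grid: for depth pairs a full grid is quadratically
large, while observed-key tables are exactly equivalent for
classification. Depths above a cap (default 400) reuse the cap's bounds,
which is conservative because bounds only narrow with depth. The
standalone `simulate-ci` command still exports dense one-bulk tables for
caching. Each depth key gets an RNG stream seeded by (seed, key), so the
table is bit-reproducible and independent of the order depths are
encountered.

A variant is flagged at level L when its statistic lies strictly outside
the bounds at its depth; a value exactly on a bound is not flagged. With
10^5-replicate tables the realized flagging rate of null data sits at or
slightly below α (the statistic is discrete at finite depth, making the
strict-inequality test mildly conservative).

### Multiple-testing correction (optional)

The correction needs three organism-level inputs: chromosome count, genome
size, and total map length in centimorgans; when any is unknown the
correction is unavailable and nominal levels are used. The effective
number of independent tests is

    m = max(n_chromosomes, round(total_cm / 50))

— loci ≥ ~50 cM apart segregate nearly independently, and chromosomes are
independent at minimum. Per-test levels are Šidák-adjusted,
α' = 1 − (1 − α)^(1/m), staying on the probability scale rather than
Bonferroni's linear bound. The m rule is a deliberate, documented choice
isolated in one function (`effective_tests`) so an alternative genome-scan
correction can be swapped in without touching the adjustment.

## Filtering

All rules are evaluated for every variant (no short-circuiting), so
per-reason rejection counts are additive and the kept set is independent
of rule order. Defaults, all configurable:

| rule | default | rationale |
|---|---|---|
| min INFO MQ | 40 | standard mpileup-era mapping-quality floor |
| per-bulk depth | 8–250 | below: index too noisy; above: repeats/CNV |
| strand bias | Phred Fisher > 40 | sequencing-artifact signature |
| parent | hom required | polarization needs a homozygous parent |
| multi-allelic | excluded | the index is a two-allele contrast; decomposing AD is ambiguous |
| indels | excluded | AD less reliable; SNP-index is defined on SNPs |
| low index, both bulks | < 0.3 (two-bulk only) | a site below 0.3 in *both* bulks carries no signal in either direction and is typically a spurious call |

Strand bias is the two-sided Fisher exact test on the 2×2
forward/reverse × ref/alt table, Phred-scaled (−10·log10 p), computed on
counts pooled over all samples that carry ADF/ADR (a site-level statistic,
matching how callers annotate strand bias); it returns 0 when any margin
is empty, and is skipped entirely when no strand counts are present. The
heterozygous-parent exclusion is toggleable since only the parent-missing
exclusion is strictly required by the model.

## Sliding windows

Windows are anchored at position 1 on every chromosome (reproducible
boundaries independent of the variant set) and advance by the step;
defaults 2 Mb window, 100 kb step, ≥ 3 variants per window. Means are
unweighted over member variants; sparser windows are emitted masked and
drawn as line gaps, never interpolated. Window CI bands are looked up at
the window's rounded mean depth from the same simulation table used for
per-variant tests.

## The synthetic-data generator

The generator emulates the full experiment: a genome of named chromosomes,
a planted causal locus, markers placed uniformly at random (or on a grid),
phenotype-selected bulk(s), linkage decay with distance, and binomial read
sampling. Map distance converts to a recombination fraction with the
Haldane function r = 0.5·(1 − e^(−2d/100)) (no interference; closed form).

Linked segregation is exact rather than approximated: an individual's
joint (causal, marker) diplotype is evolved from the F1 coupling
heterozygote through k−1 generations of selfing as a 16-state Markov chain
(4 two-locus haplotypes × ordered pairs), then conditioned on the causal
genotype class that selection fixes — homozygous non-parental for the
selected (high) bulk, homozygous parental for the low bulk. For F2 this
reduces to the familiar Binomial(2, 1−r) marker genotype given a selected
homozygote; at r = 0.5 it reduces to unlinked F_k segregation. A
penetrance parameter (default 1) mixes in unselected individuals for
partial-effect loci. Read counts are alt ~ Binomial(depth,
f·(1−e) + (1−f)·e) with f the realized finite-bulk frequency and e a
uniform per-read miscall rate (default 0). Per-site depth is fixed at the
mean, or gamma-Poisson when overdispersion > 0.

The default scenario — two 10-Mb chromosomes, causal at chr1:5,000,000,
4 cM/Mb, 20 F2 individuals per bulk, depth 100, ~2000 markers — is sized
so a full analysis runs in about a second while the causal peak is
unambiguous. The truth table records, per marker, the map distance and the
expected and realized bulk frequencies. The idealized expectation reported
by `expected_bulk_freq` uses the single-meiosis r (1 − r for the selected
bulk) even for k > 2; the realized F_k chain accumulates recombination
over generations, so for RILs the truth TSV's realized frequencies decay
faster with distance than that single-meiosis expectation — the
expectation column is a reference line, not the generative truth.

What the generator does **not** emulate: read-level artifacts (mapping
error, base-quality structure, strand bias), variant-caller genotyping
error, segregation distortion, interference, structural variants, and
non-uniform recombination maps. Passing the end-to-end tests therefore
demonstrates the statistical machinery on clean data; on real data the
filters carry the burden the generator omits.

## Numerical and design notes

* Simulation defaults: 10,000 replicates per depth (the 99% tails then
  rest on ~50 points per side; raise `--reps` for tighter tables), seed
  recorded in the run log and CI-table header; quantiles are numpy's
  default linear-interpolation empirical quantiles. Requesting a level
  whose tail would hold < 1 replicate is a configuration error.
* One-bulk bulks are F2 (`-n`); `-F` applies to the two-bulk design,
  matching the two designs' field usage. Two-sided bounds are the default
  in both modes; `--one-sided` switches the one-bulk test to
  upper-tail-only.
* Selection at the causal locus does not distort segregation at unlinked
  loci, so the null simulation deliberately ignores phenotypic selection.
* Chromosome lengths come from VCF ##contig headers; lacking those, the
  last variant position per chromosome is used.
* VCF positions are 1-based throughout; windows are 1-based inclusive.
* AD is read per the VCF spec (ref, alt1, ...); when AD is absent but
  ADF/ADR are present, AD is reconstructed as their sum; otherwise the
  call has depth 0 and is filtered.
* Outputs are deterministic at fixed seed and config: identical runs are
  byte-identical in the snp-index, window, CI and candidate tables.

## Problem sizes used in the checks

The packaged checks use desk-scale sizes chosen to make Monte-Carlo noise
negligible relative to the asserted tolerances: 10^5 replicates for null
centering and enumeration agreement (total-variation distance < 0.01),
10^5-replicate tables and 20,000 independent null variants for coverage,
and the ~2000-marker default scenario for causal recovery. The whole suite
runs in well under a minute.

## Known limitations

* Multi-allelic sites are excluded, not decomposed.
* The ΔSNP-index null treats bulks as independent; shared-parent linkage
  disequilibrium between bulks is not modeled (standard for this class of
  analysis).
* The effective-test rule for the correction is a documented heuristic;
  organisms with very long or very short maps may warrant a different m.
* SnpEff is consumed (ANN field), never executed; annotation is display
  metadata only.
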