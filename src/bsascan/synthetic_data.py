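"""Synthetic parent + bulk VCFs from a diploid biparental cross.

Generates the data a bulked-segregant experiment would produce — a
homozygous parent, one phenotype-selected bulk (mutant-mapping design) or
two opposite bulks (QTL-seq design), markers with linkage decay around a
planted causal locus, and binomial read sampling at realistic depth — so
the whole pipeline is testable without external downloads.  Doubles as a
power-exploration simulator.

Linked segregation is exact, not approximated: each bulked individual's
genotype at a marker is drawn from the two-locus (causal, marker) diplotype
distribution obtained by iterating the selfing transition from F1 for the
configured number of generations and conditioning on the causal genotype
the phenotypic selection fixes.  Map distances convert to recombination
fractions with the Haldane function (no interference).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .null_simulation import BulkDesign, segregation_probs
from .vcf_io import GenomeInfo

BASES = "ACGT"


def haldane_r(d_cm: float) -> float:
    """Recombination fraction from map distance (cM), Haldane map function."""
    if math.isinf(d_cm):
        return 0.5
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


@dataclass
class SyntheticScenario:
    """Full description of a simulated cross and sequencing experiment.

    mode:
        "one-bulk" — a single bulk selected homozygous for the non-parental
        allele at the causal locus; "two-bulk" — high and low bulks fixed in
        opposite directions at the causal locus.
    cm_per_mb:
        Uniform recombination rate (default 4 cM/Mb, a typical plant-genome
        average).
    depth_mean / depth_overdispersion:
        Per-site per-sample depth model: fixed at depth_mean when
        overdispersion is 0, else gamma-Poisson (negative binomial) with
        variance mean + overdispersion * mean**2.
    error_rate:
        Per-read miscall probability flipping a read between alleles.
    penetrance:
        Probability that a bulked individual truly carries the selected
        causal genotype (1 = ideal truncation selection).
    """

    genome: GenomeInfo
    causal: tuple[str, int]
    designs: tuple[BulkDesign, ...]
    mode: str = "one-bulk"
    cm_per_mb: float = 4.0
    n_variants: int = 2000
    depth_mean: float = 100.0
    depth_overdispersion: float = 0.0
    error_rate: float = 0.0
    penetrance: float = 1.0
    marker_placement: str = "uniform"  # or "grid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("one-bulk", "two-bulk"):
            raise ValueError("mode must be 'one-bulk' or 'two-bulk'")
        if len(self.designs) != (1 if self.mode == "one-bulk" else 2):
            raise ValueError(f"{self.mode} mode requires "
                             f"{1 if self.mode == 'one-bulk' else 2} bulk design(s)")
        chrom, pos = self.causal
        if not 1 <= pos <= self.genome.length_of(chrom):
            raise ValueError("causal position outside its chromosome")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in (0, 1]")


def default_scenario(mode: str = "one-bulk", seed: int = 0, **overrides) -> SyntheticScenario:
    """The reference desk-scale scenario: one 10-Mb chromosome carrying the
    causal locus at 5 Mb plus one unlinked 10-Mb chromosome, 20 F2
    individuals per bulk, depth 100, 2000 markers."""
    genome = GenomeInfo(chromosomes=(("chr1", 10_000_000), ("chr2", 10_000_000)),
                        total_cm=80.0)
    designs = ((BulkDesign(20, 2),) if mode == "one-bulk"
               else (BulkDesign(20, 2), BulkDesign(20, 2)))
    params = dict(genome=genome, causal=("chr1", 5_000_000), designs=designs,
                  mode=mode, seed=seed)
    params.update(overrides)
    return SyntheticScenario(**params)


def marker_distance_cm(chrom: str, pos: int, scenario: SyntheticScenario) -> float:
    """Map distance (cM) from a marker to the causal locus; inf across chromosomes."""
    c_chrom, c_pos = scenario.causal
    if chrom != c_chrom:
        return math.inf
    return scenario.cm_per_mb * abs(pos - c_pos) / 1e6


def expected_bulk_freq(chrom: str, pos: int, scenario: SyntheticScenario) -> tuple[float, ...]:
    """Idealized expected non-parental allele frequency per bulk.

    With recombination fraction r to the causal locus, a bulk fixed for the
    non-parental causal allele expects frequency 1 - r at the marker; the
    opposite bulk expects r.  Unlinked markers (r = 0.5) give 0.5.
    """
    r = haldane_r(marker_distance_cm(chrom, pos, scenario))
    if scenario.mode == "one-bulk":
        return (1.0 - r,)
    return (1.0 - r, r)


# ---------------------------------------------------------------------------
# Two-locus diplotype chain: exact linked segregation through selfing.
# Haplotypes are 2-bit codes (causal_allele, marker_allele); a diplotype is
# an ordered haplotype pair giving 16 states.  Alleles: 0 parental,
# 1 non-parental.

def _selfing_matrix(r: float) -> np.ndarray:
    T = np.zeros((16, 16))
    for h1 in range(4):
        for h2 in range(4):
            a = (h1 >> 1, h2 >> 1)  # causal alleles of the two haplotypes
            b = (h1 & 1, h2 & 1)    # marker alleles
            gam = np.zeros(4)
            for i in (0, 1):
                for j in (0, 1):
                    p = 0.5 * ((1 - r) if i == j else r)
                    gam[(a[i] << 1) | b[j]] += p
            T[h1 * 4 + h2] = np.outer(gam, gam).ravel()
    return T


def linked_genotype_probs(r: float, generation_k: int,
                          causal_count: Optional[int]) -> np.ndarray:
    """P(marker non-parental allele count = 0,1,2) for one F_k individual.

    Conditioned on the individual carrying ``causal_count`` non-parental
    alleles at the causal locus (None = unconditional).  Computed exactly
    from the diplotype chain: F1 is the coupling heterozygote and each
    generation applies one selfing transition.
    """
    if generation_k < 2:
        raise ValueError("generation must be >= 2")
    v = np.zeros(16)
    v[0 * 4 + 3] = 1.0  # F1: one fully parental, one fully non-parental haplotype
    T = _selfing_matrix(r)
    for _ in range(generation_k - 1):
        v = v @ T
    states = np.arange(16)
    causal = (states // 4 >> 1) + (states % 4 >> 1)
    marker = (states // 4 & 1) + (states % 4 & 1)
    if causal_count is not None:
        mask = causal == causal_count
        total = v[mask].sum()
        if total <= 0:
            raise ValueError(f"causal genotype class {causal_count} has probability 0")
        weights = np.where(mask, v, 0.0) / total
    else:
        weights = v
    return np.array([weights[marker == c].sum() for c in range(3)])


def _bulk_marker_freq(r: float, design: BulkDesign, causal_count: Optional[int],
                      penetrance: float, rng: np.random.Generator) -> float:
    """Realized non-parental frequency of one finite bulk at one marker."""
    cond = linked_genotype_probs(r, design.generation, causal_count)
    if penetrance < 1.0 and causal_count is not None:
        uncond = linked_genotype_probs(r, design.generation, None)
        cond = penetrance * cond + (1.0 - penetrance) * uncond
    counts = rng.multinomial(design.n_individuals, cond)
    return (counts[1] + 2 * counts[2]) / (2 * design.n_individuals)


def _marker_positions(scenario: SyntheticScenario, rng: np.random.Generator) -> list[tuple[str, int]]:
    genome_size = scenario.genome.genome_size_bp
    out: list[tuple[str, int]] = []
    c_chrom, c_pos = scenario.causal
    for chrom, length in scenario.genome.chromosomes:
        n = max(1, round(scenario.n_variants * length / genome_size))
        if scenario.marker_placement == "grid":
            pos = np.linspace(1, length, n, dtype=np.int64)
        else:
            pos = rng.choice(length, size=min(n, length), replace=False) + 1
        pos = set(int(p) for p in pos)
        if chrom == c_chrom:
            pos.add(c_pos)  # the causal site is always itself a marker
        out.extend((chrom, p) for p in sorted(pos))
    return out


def generate_vcf(scenario: SyntheticScenario) -> tuple[str, list[dict]]:
    """Simulate the experiment and return (VCF text, truth table rows).

    The VCF carries the parent plus one or two bulk samples with GT and AD;
    the parent is always homozygous reference at full depth.  Bulk alt
    depths are Binomial(depth, f*(1-e) + (1-f)*e) where f is the realized
    finite-bulk frequency at the marker and e the per-read error rate.
    Truth rows record, per marker, the map distance to the causal locus and
    the expected and realized bulk frequencies.
    """
    rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 0xB5A)))
    n_bulks = len(scenario.designs)
    sample_names = ["PARENT"] + [f"BULK{i+1}" for i in range(n_bulks)]
    causal_classes = (2,) if scenario.mode == "one-bulk" else (2, 0)

    header = io.StringIO()
    header.write("##fileformat=VCFv4.2\n")
    header.write(f"##bsascan_scenario_seed={scenario.seed}\n")
    for chrom, length in scenario.genome.chromosomes:
        header.write(f"##contig=<ID={chrom},length={length}>\n")
    header.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
    header.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    header.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
    header.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")

    def draw_depth() -> int:
        if scenario.depth_overdispersion <= 0:
            return max(1, int(round(scenario.depth_mean)))
        od = scenario.depth_overdispersion
        lam = rng.gamma(shape=1.0 / od, scale=scenario.depth_mean * od)
        return int(rng.poisson(lam))

    body = io.StringIO()
    truth: list[dict] = []
    for chrom, pos in _marker_positions(scenario, rng):
        d_cm = marker_distance_cm(chrom, pos, scenario)
        r = haldane_r(d_cm)
        ref = BASES[rng.integers(4)]
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4]
        exp_f = expected_bulk_freq(chrom, pos, scenario)

        parent_depth = draw_depth()
        calls = [f"0/0:{parent_depth},0"]
        row = {"CHROM": chrom, "POS": pos, "DIST_CM": d_cm}
        for b, (design, causal_count) in enumerate(zip(scenario.designs, causal_classes)):
            f = _bulk_marker_freq(r, design, causal_count, scenario.penetrance, rng)
            depth = draw_depth()
            e = scenario.error_rate
            alt_reads = int(rng.binomial(depth, f * (1 - e) + (1 - f) * e)) if depth else 0
            ref_reads = depth - alt_reads
            if depth == 0:
                gt = "./."
            else:
                idx = alt_reads / depth
                gt = "1/1" if idx > 0.9 else ("0/0" if idx < 0.1 else "0/1")
            calls.append(f"{gt}:{ref_reads},{alt_reads}")
            row[f"EXP_FREQ_BULK{b+1}"] = exp_f[b]
            row[f"TRUE_FREQ_BULK{b+1}"] = f
        truth.append(row)
        body.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\tMQ=60\tGT:AD\t"
                   + "\t".join(calls) + "\n")

    return header.getvalue() + body.getvalue(), truth


def write_scenario(scenario: SyntheticScenario, vcf_path: str, truth_path: str) -> None:
    """Write the simulated VCF and its truth table (TSV) to disk."""
    vcf_text, truth = generate_vcf(scenario)
    with open(vcf_path, "w") as fh:
        fh.write(vcf_text)
    cols = list(truth[0].keys()) if truth else ["CHROM", "POS", "DIST_CM"]
    with open(truth_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth:
            fields = []
            for c in cols:
                v = row[c]
                fields.append(f"{v:.6f}" if isinstance(v, float) else str(v))
            fh.write("\t".join(fields) + "\n")
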