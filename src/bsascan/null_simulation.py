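"""Monte-Carlo null distribution of the SNP-index and delta SNP-index.

At a locus unlinked to the selected trait, the bulk's non-parental allele
frequency is set by Mendelian segregation in the cross generation, and the
observed SNP-index adds binomial read-sampling noise on top of it.  The
null hypothesis of "no linkage" is therefore simulated directly — bulk
composition drawn from the segregation model, reads drawn binomially at the
site's depth — with no distributional assumption on the index itself.
Because read depth varies strongly among sites, confidence bounds are
computed per depth.

The significance test is two-sided by default; one-sided (upper-tail)
bounds for the one-bulk statistic are available via ``two_sided=False``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence, Union

import numpy as np

DEFAULT_LEVELS = (0.95, 0.99)
DEFAULT_REPS = 10_000
DEFAULT_DEPTH_CAP = 400


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class BulkDesign:
    """Bulk composition: number of pooled individuals and cross generation.

    ``generation`` k >= 2 selects the selfing generation F_k: F2 progeny
    (k=2) or recombinant inbred lines for large k.  Ploidy is fixed at 2.
    """

    n_individuals: int
    generation: int = 2

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise SimulationConfigError("n_individuals must be >= 1")
        if self.generation < 2:
            raise SimulationConfigError("generation must be >= 2 (F2 or later)")


DesignOrPair = Union[BulkDesign, tuple[BulkDesign, BulkDesign]]


@dataclass(frozen=True)
class SegregationModel:
    """Genotype probabilities of one F_k individual at an unlinked locus."""

    p_hom_parent: float
    p_het: float
    p_hom_nonparent: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_hom_parent, self.p_het, self.p_hom_nonparent])


def segregation_probs(generation_k: int) -> SegregationModel:
    """Mendelian genotype ratios after k-2 generations of selfing from F2.

    Heterozygosity halves each selfing generation: h_k = 0.5**(k-1), giving
    (1/4, 1/2, 1/4) at F2 and approaching (1/2, 0, 1/2) for fully inbred
    lines.  The two homozygote classes are equal by symmetry.
    """
    if generation_k < 2:
        raise SimulationConfigError("generation must be >= 2")
    p_het = 0.5 ** (generation_k - 1)
    p_hom = (1.0 - p_het) / 2.0
    return SegregationModel(p_hom_parent=p_hom, p_het=p_het, p_hom_nonparent=p_hom)


def sample_bulk_freq(design: BulkDesign, rng: np.random.Generator,
                     size: Optional[int] = None) -> Union[float, np.ndarray]:
    """Draw the pooled non-parental allele frequency of one bulk.

    Each of the n individuals contributes 0, 1 or 2 non-parental alleles
    according to the segregation model; the frequency is the pooled count
    over 2n chromosomes.  With ``size`` an array of independent draws is
    returned.
    """
    probs = segregation_probs(design.generation).as_array()
    n = design.n_individuals
    counts = rng.multinomial(n, probs, size=size)
    freq = (counts[..., 1] + 2 * counts[..., 2]) / (2 * n)
    return freq if size is not None else float(freq)


def simulate_null_statistic(
    depth: Union[int, tuple[int, int]],
    design_or_pair: DesignOrPair,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the null statistic at fixed depth.

    One-bulk mode (a single :class:`BulkDesign`): each replicate draws a
    bulk frequency p and an observed index Binomial(depth, p)/depth.
    Two-bulk mode (a pair of designs, depth an int applied to both or a
    (depth1, depth2) pair): the two bulks are drawn independently and the
    statistic is index1 - index2.
    """
    if reps < 1:
        raise SimulationConfigError("reps must be >= 1")
    if isinstance(design_or_pair, BulkDesign):
        d = int(depth)
        if d < 1:
            raise SimulationConfigError("depth must be >= 1")
        p = sample_bulk_freq(design_or_pair, rng, size=reps)
        return rng.binomial(d, p) / d
    d1, d2 = (depth, depth) if isinstance(depth, (int, np.integer)) else depth
    if d1 < 1 or d2 < 1:
        raise SimulationConfigError("depth must be >= 1 in both bulks")
    des1, des2 = design_or_pair
    p1 = sample_bulk_freq(des1, rng, size=reps)
    p2 = sample_bulk_freq(des2, rng, size=reps)
    return rng.binomial(int(d1), p1) / d1 - rng.binomial(int(d2), p2) / d2


def exact_null_distribution(depth: Union[int, tuple[int, int]],
                            design_or_pair: DesignOrPair) -> dict[float, float]:
    """Exact null distribution by full enumeration (desk-scale designs only).

    Enumerates every genotype configuration of the bulk(s) and every
    binomial read outcome; feasible for small n and depth, and used as the
    independent check of the Monte-Carlo simulation.
    """
    from scipy.stats import binom

    def one_bulk(d: int, design: BulkDesign) -> dict[float, float]:
        probs = segregation_probs(design.generation).as_array()
        n = design.n_individuals
        dist: dict[float, float] = {}
        # genotype configuration = count of non-parental alleles per individual
        for combo in product(range(3), repeat=n):
            p_combo = math.prod(probs[g] for g in combo)
            f = sum(combo) / (2 * n)
            for k in range(d + 1):
                stat = k / d
                dist[stat] = dist.get(stat, 0.0) + p_combo * binom.pmf(k, d, f)
        return dist

    if isinstance(design_or_pair, BulkDesign):
        return one_bulk(int(depth), design_or_pair)
    d1, d2 = (depth, depth) if isinstance(depth, (int, np.integer)) else depth
    des1, des2 = design_or_pair
    dist1 = one_bulk(int(d1), des1)
    dist2 = one_bulk(int(d2), des2)
    out: dict[float, float] = {}
    for s1, p1 in dist1.items():
        for s2, p2 in dist2.items():
            s = round(s1 - s2, 12)
            out[s] = out.get(s, 0.0) + p1 * p2
    return out


def _depth_key(depth) -> tuple[int, ...]:
    if isinstance(depth, (int, np.integer)):
        return (int(depth),)
    return tuple(int(d) for d in depth)


@dataclass
class CITable:
    """Per-depth empirical confidence bounds of the null statistic.

    ``bounds`` maps a depth key — ``(depth,)`` in one-bulk mode, ``(depth1,
    depth2)`` in two-bulk mode — to ``{level: (lower, upper)}``.  Lookups at
    depths beyond the table cap are served by the capped depth, which is
    conservative because bounds narrow with depth.
    """

    mode: str  # "one-bulk" | "two-bulk"
    designs: DesignOrPair
    levels: tuple[float, ...]
    reps: int
    seed: int
    depth_cap: int
    bounds: dict[tuple[int, ...], dict[float, tuple[float, float]]] = field(default_factory=dict)

    def cap_key(self, depth) -> tuple[int, ...]:
        return tuple(min(d, self.depth_cap) for d in _depth_key(depth))

    def lookup(self, depth, level: float) -> tuple[float, float]:
        key = self.cap_key(depth)
        try:
            return self.bounds[key][level]
        except KeyError as exc:
            raise KeyError(
                f"CI table has no bounds for depth {key} at level {level}") from exc

    def to_tsv(self, sink) -> None:
        two = self.mode == "two-bulk"
        sink.write(f"# mode={self.mode} reps={self.reps} seed={self.seed} "
                   f"depth_cap={self.depth_cap}\n")
        header = (["DEPTH1", "DEPTH2"] if two else ["DEPTH"]) + ["LEVEL", "LOWER", "UPPER"]
        sink.write("\t".join(header) + "\n")
        for key in sorted(self.bounds):
            for lv in self.levels:
                lo, hi = self.bounds[key][lv]
                row = [str(d) for d in key] + [f"{lv:g}", f"{lo:.6f}", f"{hi:.6f}"]
                sink.write("\t".join(row) + "\n")


def _rng_for(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    # Keyed by depth so the table is identical however depths are ordered.
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def build_ci_table(
    depths: Iterable,
    design_or_pair: DesignOrPair,
    levels: Sequence[float] = DEFAULT_LEVELS,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    depth_cap: int = DEFAULT_DEPTH_CAP,
    two_sided: bool = True,
) -> CITable:
    """Build a :class:`CITable` at the given depths.

    Bounds at level L are the (1-L)/2 and 1-(1-L)/2 empirical quantiles of
    the simulated null statistic (upper quantile at L with lower bound
    -inf/0 when ``two_sided`` is False).  Deterministic given ``seed``:
    each depth gets an RNG stream keyed by (seed, depth).
    """
    levels = tuple(sorted(levels))
    if not levels or any(not 0 < lv < 1 for lv in levels):
        raise SimulationConfigError("levels must lie strictly in (0, 1)")
    for lv in levels:
        if reps * (1 - lv) / 2 < 1:
            raise SimulationConfigError(
                f"reps={reps} too small for the {lv:g} quantile tails; "
                f"need reps >= {math.ceil(2 / (1 - lv))}")
    mode = "one-bulk" if isinstance(design_or_pair, BulkDesign) else "two-bulk"
    table = CITable(mode=mode, designs=design_or_pair, levels=levels,
                    reps=reps, seed=seed, depth_cap=depth_cap)
    seen = set()
    for depth in depths:
        key = tuple(min(d, depth_cap) for d in _depth_key(depth))
        if key in seen:
            continue
        seen.add(key)
        rng = _rng_for(seed, key)
        sims = simulate_null_statistic(key[0] if mode == "one-bulk" else key,
                                       design_or_pair, reps, rng)
        sims.sort()
        per_level = {}
        for lv in levels:
            alpha = 1 - lv
            if two_sided:
                lo = float(np.quantile(sims, alpha / 2))
                hi = float(np.quantile(sims, 1 - alpha / 2))
            else:
                lo = -1.0 if mode == "two-bulk" else 0.0
                hi = float(np.quantile(sims, 1 - alpha))
            per_level[lv] = (lo, hi)
        table.bounds[key] = per_level
    return table


@dataclass(frozen=True)
class CorrectionInput:
    """Biological inputs for the optional multiple-testing correction.

    All three fields are required; when any is unknown for the organism the
    correction is simply unavailable and uncorrected levels are used.
    """

    n_chromosomes: int
    genome_size_bp: int
    total_cm: float

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.genome_size_bp <= 0 or self.total_cm <= 0:
            raise SimulationConfigError("correction inputs must all be positive")


def effective_tests(correction: CorrectionInput) -> int:
    """Effective number of independent tests across the genome.

    Loci ~50 cM apart segregate near-independently, so the map length in
    50-cM blocks bounds the number of independent genomic regions from
    below by the chromosome count.  Isolated here so the rule can be
    swapped without touching the adjustment.
    """
    m = max(correction.n_chromosomes, round(correction.total_cm / 50.0))
    if m < 1:
        raise SimulationConfigError("effective test count must be >= 1")
    return int(m)


def corrected_levels(base_levels: Sequence[float],
                     correction: Optional[CorrectionInput]) -> tuple[float, ...]:
    """Sidak-adjust confidence levels for the effective number of tests.

    Per-test tail mass alpha' = 1 - (1 - alpha)**(1/m) with alpha = 1 - L,
    returned as adjusted levels 1 - alpha'.  With m = 1 the input levels
    are returned unchanged.
    """
    if correction is None:
        raise SimulationConfigError(
            "multiple-testing correction requires number of chromosomes, genome "
            "size, and total centimorgans; correction is unavailable without them")
    m = effective_tests(correction)
    out = []
    for lv in base_levels:
        if not 0 < lv < 1:
            raise SimulationConfigError("levels must lie strictly in (0, 1)")
        alpha = 1.0 - lv
        alpha_adj = 1.0 - (1.0 - alpha) ** (1.0 / m)
        out.append(1.0 - alpha_adj)
    return tuple(out)


def classify(indexed_variant, ci_table: CITable,
             levels: Optional[Sequence[float]] = None) -> dict[float, bool]:
    """Flag a variant whose statistic lies strictly outside the null CI.

    Fills ``indexed_variant.flags`` and ``.ci`` per level and returns the
    flag map.  A statistic exactly on a bound is not flagged.
    """
    levels = tuple(levels) if levels is not None else ci_table.levels
    stat = indexed_variant.statistic
    for lv in levels:
        lo, hi = ci_table.lookup(indexed_variant.depth_key, lv)
        indexed_variant.ci[lv] = (lo, hi)
        indexed_variant.flags[lv] = bool(stat < lo or stat > hi)
    return indexed_variant.flags


def attach_window_ci(windows, ci_table: CITable) -> None:
    """Attach per-level CI bounds at the (rounded) mean depth to windows."""
    for w in windows:
        if w.masked or w.mean_depth is None:
            continue
        depth = tuple(max(1, int(round(d))) for d in w.mean_depth)
        key = depth[0] if len(depth) == 1 else depth
        for lv in ci_table.levels:
            try:
                w.ci[lv] = ci_table.lookup(key, lv)
            except KeyError:
                pass  # table built without this window's depth: leave blank
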