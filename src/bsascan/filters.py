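"""Variant-level exclusion rules applied before SNP-index analysis.

Low-quality sites are removed on mapping quality and strand bias; sites
where the parental call is missing are ignored because the index cannot be
polarized without a parent.  Every rule is evaluated for every variant (no
short-circuiting) so rejection counts per reason are additive and
order-independent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

from scipy.stats import fisher_exact

from .bsa_stats import polarized_bulk_depths, snp_index
from .vcf_io import Variant

Mode = Literal["one-bulk", "two-bulk"]

#: Machine-readable rejection codes.
MISSING_PARENT = "MISSING_PARENT"
PARENT_HET = "PARENT_HET"
MULTIALLELIC = "MULTIALLELIC"
INDEL = "INDEL"
LOW_MQ = "LOW_MQ"
STRAND_BIAS = "STRAND_BIAS"
LOW_DEPTH = "LOW_DEPTH"
HIGH_DEPTH = "HIGH_DEPTH"
LOW_INDEX_BOTH_BULKS = "LOW_INDEX_BOTH_BULKS"

ALL_REASONS = (MISSING_PARENT, PARENT_HET, MULTIALLELIC, INDEL, LOW_MQ,
               STRAND_BIAS, LOW_DEPTH, HIGH_DEPTH, LOW_INDEX_BOTH_BULKS)


@dataclass
class FilterConfig:
    """Thresholds for variant exclusion.

    min_mq:
        Minimum INFO MQ (RMS mapping quality); sites below are rejected.
    min_depth, max_depth:
        Per-bulk total-depth bounds (reads); either bound violated by any
        bulk rejects the site.
    strand_bias_phred_max:
        Phred-scaled Fisher-exact strand-bias cutoff, applied only when
        per-strand depths (ADF/ADR) are present.
    min_index_either_bulk:
        Two-bulk mode only: reject sites whose SNP-index is below this in
        *every* bulk — such sites cannot carry signal in either direction
        and are typically spurious calls.
    exclude_indels, parent_hom_required:
        Restrict to SNPs / to sites where the parent is homozygous.
    """

    min_mq: float = 40.0
    min_depth: int = 8
    max_depth: int = 250
    strand_bias_phred_max: float = 40.0
    min_index_either_bulk: float = 0.3
    exclude_indels: bool = True
    parent_hom_required: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_depth <= self.max_depth:
            raise ValueError("require 0 <= min_depth <= max_depth")
        for name in ("min_mq", "strand_bias_phred_max", "min_index_either_bulk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FilterVerdict:
    reasons: list[str] = field(default_factory=list)

    @property
    def keep(self) -> bool:
        return not self.reasons


def strand_bias_phred(adf_ref: int, adr_ref: int, adf_alt: int, adr_alt: int) -> float:
    """Phred-scaled two-sided Fisher exact test on the strand 2x2 table.

    The table is [[adf_ref, adr_ref], [adf_alt, adr_alt]].  Returns
    -10*log10(p).  When any margin is zero the test is undefined and 0 is
    returned (no evidence of bias).
    """
    counts = (adf_ref, adr_ref, adf_alt, adr_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"strand counts must be non-negative, got {counts}")
    if (adf_ref + adr_ref == 0 or adf_alt + adr_alt == 0
            or adf_ref + adf_alt == 0 or adr_ref + adr_alt == 0):
        return 0.0
    _, p = fisher_exact([[adf_ref, adr_ref], [adf_alt, adr_alt]], alternative="two-sided")
    if p <= 0:  # numerically impossible for finite tables, but be safe
        return math.inf
    return max(0.0, -10.0 * math.log10(p))


def _pooled_strand_counts(variant: Variant):
    """Site-level strand table pooled over all samples carrying ADF/ADR."""
    calls = [variant.parent, *variant.bulks]
    with_strand = [c for c in calls if c.has_strand_counts]
    if not with_strand:
        return None
    return (
        sum(c.adf_ref for c in with_strand),
        sum(c.adr_ref for c in with_strand),
        sum(c.adf_alt for c in with_strand),
        sum(c.adr_alt for c in with_strand),
    )


def apply_filters(variant: Variant, config: FilterConfig, mode: Mode) -> FilterVerdict:
    """Evaluate every exclusion rule and return the full list of violations."""
    reasons: list[str] = []

    parent = variant.parent
    if parent.is_missing or parent.depth == 0:
        reasons.append(MISSING_PARENT)
    elif parent.is_het and config.parent_hom_required:
        reasons.append(PARENT_HET)

    if variant.is_multiallelic:
        reasons.append(MULTIALLELIC)
    if config.exclude_indels and not variant.is_snp:
        reasons.append(INDEL)
    if variant.mq is not None and variant.mq < config.min_mq:
        reasons.append(LOW_MQ)

    pooled = _pooled_strand_counts(variant)
    if pooled is not None:
        fr, rr, fa, ra = pooled
        if strand_bias_phred(fr, rr, fa, ra) > config.strand_bias_phred_max:
            reasons.append(STRAND_BIAS)

    pairs = polarized_bulk_depths(variant)
    depths = [r + a for r, a in pairs]
    if any(d < config.min_depth for d in depths):
        reasons.append(LOW_DEPTH)
    if any(d > config.max_depth for d in depths):
        reasons.append(HIGH_DEPTH)

    if mode == "two-bulk" and not variant.is_multiallelic and all(d >= 1 for d in depths):
        indices = [snp_index(r, a) for r, a in pairs]
        if all(ix < config.min_index_either_bulk for ix in indices):
            reasons.append(LOW_INDEX_BOTH_BULKS)

    return FilterVerdict(reasons=reasons)


def summarize_verdicts(verdicts: Iterable[FilterVerdict]) -> Counter:
    """Counts per rejection reason plus totals, for the run log."""
    counts: Counter = Counter()
    for v in verdicts:
        counts["TOTAL"] += 1
        if v.keep:
            counts["KEPT"] += 1
        for r in v.reasons:
            counts[r] += 1
    return counts


def format_filter_summary(counts: Counter) -> str:
    parts = [f"total={counts.get('TOTAL', 0)}", f"kept={counts.get('KEPT', 0)}"]
    parts += [f"{r}={counts[r]}" for r in ALL_REASONS if counts.get(r)]
    return "filter summary: " + " ".join(parts)
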