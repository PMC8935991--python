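"""SNP-index, delta SNP-index, and sliding-window genome-scan summaries.

The SNP-index of a pooled sample at a site is the fraction of reads carrying
the allele *absent from the sequenced parent*: 0.5 is expected at loci
unlinked to the selected trait in an F2 bulk, and 1.0 at a causal locus in a
bulk selected for the homozygous non-parental genotype.  The delta SNP-index
contrasts two opposite-phenotype bulks and is 0 under no linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .vcf_io import GenomeInfo, Variant


class UndefinedIndexError(ValueError):
    """SNP-index requested at zero depth."""


class OrderingError(ValueError):
    """Variants were not sorted by (chrom, pos)."""


def snp_index(ad_ref: int, ad_alt: int) -> float:
    """Fraction of reads carrying the non-parental allele.

    Callers must already have polarized the depths so that ``ad_alt`` counts
    the allele absent from the parent (see :func:`polarized_bulk_depths`).
    """
    depth = ad_ref + ad_alt
    if depth < 1:
        raise UndefinedIndexError("SNP-index undefined at zero depth")
    return ad_alt / depth


def delta_snp_index(index_bulk1: float, index_bulk2: float) -> float:
    """SNP-index difference, first-configured bulk minus the second."""
    return index_bulk1 - index_bulk2


def polarized_bulk_depths(variant: Variant) -> list[tuple[int, int]]:
    """Per-bulk (ref-like, nonparental) depth pairs.

    The tracked allele is the one the homozygous parent does not carry.  A
    parent called homozygous for the first alternate allele flips the
    orientation: ref and alt depths are swapped so the index still measures
    the non-parental allele.  Parents that are missing or heterozygous
    (filtered upstream in normal operation) default to reference
    orientation.
    """
    swap = variant.parent.genotype == (1, 1)
    out = []
    for b in variant.bulks:
        out.append((b.ad_alt, b.ad_ref) if swap else (b.ad_ref, b.ad_alt))
    return out


@dataclass
class IndexedVariant:
    """A variant reduced to its genome-scan statistics.

    ``flags`` maps a confidence level to True when the statistic falls
    outside the null confidence interval at that level (filled by
    :func:`bsascan.null_simulation.classify`); ``ci`` holds the bounds used.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depths: tuple[int, ...]
    indices: tuple[float, ...]
    delta: Optional[float] = None
    flags: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    ann: Optional[str] = None

    @property
    def statistic(self) -> float:
        """The tested quantity: SNP-index (one bulk) or delta (two bulks)."""
        return self.delta if self.delta is not None else self.indices[0]

    @property
    def depth_key(self):
        return self.depths[0] if len(self.depths) == 1 else tuple(self.depths)


def index_variant(variant: Variant) -> IndexedVariant:
    """Compute per-bulk SNP-indices (and delta for two bulks) for one variant."""
    pairs = polarized_bulk_depths(variant)
    depths = tuple(r + a for r, a in pairs)
    indices = tuple(snp_index(r, a) for r, a in pairs)
    delta = delta_snp_index(indices[0], indices[1]) if len(indices) == 2 else None
    return IndexedVariant(
        chrom=variant.chrom, pos=variant.pos, ref=variant.ref,
        alt=variant.alts[0], depths=depths, indices=indices, delta=delta,
        ann=variant.ann,
    )


@dataclass
class WindowRecord:
    """Sliding-window summary over member variants.

    ``start``/``end`` are 1-based inclusive.  Means are unweighted
    arithmetic means over member variants and are None (masked) when fewer
    than the configured minimum number of variants fall in the window.
    """

    chrom: str
    start: int
    end: int
    n_variants: int
    masked: bool
    mean_depth: Optional[tuple[float, ...]] = None
    mean_index: Optional[tuple[float, ...]] = None
    mean_delta: Optional[float] = None
    ci: dict = field(default_factory=dict)

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    @property
    def statistic(self) -> Optional[float]:
        if self.masked:
            return None
        return self.mean_delta if self.mean_delta is not None else self.mean_index[0]


def sliding_windows(
    indexed_variants: Sequence[IndexedVariant],
    window_bp: int,
    step_bp: int,
    min_variants: int,
    genome: GenomeInfo,
) -> Iterator[WindowRecord]:
    """Yield fixed-width windows anchored at position 1 on every chromosome.

    Windows start at 1, 1+step, 1+2*step, ... while the start lies within
    the chromosome; a variant at position p belongs to window
    [s, s+window_bp-1] iff s <= p <= s+window_bp-1, so interior variants are
    shared by ceil(window_bp/step_bp) overlapping windows.  Input must be
    sorted by (chrom, pos) in genome chromosome order.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("require window_bp >= step_bp >= 1")

    by_chrom: dict[str, list[IndexedVariant]] = {name: [] for name, _ in genome.chromosomes}
    order = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
    last = (-1, -1)
    for v in indexed_variants:
        if v.chrom not in by_chrom:
            raise OrderingError(f"variant chromosome {v.chrom!r} not in genome")
        key = (order[v.chrom], v.pos)
        if key < last:
            raise OrderingError(f"variants not sorted at {v.chrom}:{v.pos}")
        last = key
        by_chrom[v.chrom].append(v)

    for chrom, length in genome.chromosomes:
        members = by_chrom[chrom]
        pos = np.array([v.pos for v in members], dtype=np.int64)
        n_bulks = len(members[0].depths) if members else 1
        depths = np.array([v.depths for v in members], dtype=float).reshape(len(members), n_bulks)
        indices = np.array([v.indices for v in members], dtype=float).reshape(len(members), n_bulks)
        deltas = (np.array([v.delta for v in members], dtype=float)
                  if members and members[0].delta is not None else None)

        start = 1
        while start <= length:
            end = min(start + window_bp - 1, length)
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, start + window_bp - 1, side="right"))
            n = hi - lo
            if n < min_variants:
                yield WindowRecord(chrom=chrom, start=start, end=end,
                                   n_variants=n, masked=True)
            else:
                yield WindowRecord(
                    chrom=chrom, start=start, end=end, n_variants=n, masked=False,
                    mean_depth=tuple(depths[lo:hi].mean(axis=0)),
                    mean_index=tuple(indices[lo:hi].mean(axis=0)),
                    mean_delta=float(deltas[lo:hi].mean()) if deltas is not None else None,
                )
            start += step_bp


def write_window_table(windows: Iterable[WindowRecord], sink, levels: Sequence[float] = ()) -> None:
    """TSV export of window records; masked windows keep NA statistics."""
    windows = list(windows)
    n_bulks = max((len(w.mean_depth) for w in windows if not w.masked), default=1)
    cols = ["CHROM", "START", "END", "N_VARIANTS"]
    for b in range(1, n_bulks + 1):
        cols += [f"BULK{b}_MEAN_DEPTH", f"BULK{b}_MEAN_INDEX"]
    if any(w.mean_delta is not None for w in windows):
        cols.append("MEAN_DELTA")
        has_delta = True
    else:
        has_delta = False
    for lv in levels:
        cols += [f"CI{lv:g}_LOWER", f"CI{lv:g}_UPPER"]
    cols.append("MASKED")
    sink.write("\t".join(cols) + "\n")
    for w in windows:
        fields = [w.chrom, str(w.start), str(w.end), str(w.n_variants)]
        if w.masked:
            fields += ["NA", "NA"] * n_bulks
            if has_delta:
                fields.append("NA")
            fields += ["NA", "NA"] * len(levels)
        else:
            for d, ix in zip(w.mean_depth, w.mean_index):
                fields += [f"{d:.4f}", f"{ix:.4f}"]
            if has_delta:
                fields.append(f"{w.mean_delta:.4f}" if w.mean_delta is not None else "NA")
            for lv in levels:
                if lv in w.ci:
                    lo, hi = w.ci[lv]
                    fields += [f"{lo:.4f}", f"{hi:.4f}"]
                else:
                    fields += ["NA", "NA"]
        fields.append("1" if w.masked else "0")
        sink.write("\t".join(fields) + "\n")
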