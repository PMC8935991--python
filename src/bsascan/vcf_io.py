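"""Read multi-sample VCFs into the internal variant model and write tabular output.

Bulked-segregant analysis consumes a VCF holding one parental sample and one
(mutant-bulk mapping) or two (QTL-seq style) pooled-progeny samples.  Only the
GT and AD FORMAT fields are required; per-strand depths (ADF/ADR) and the INFO
MQ field are used by downstream filters when present.

Coordinates are 1-based throughout, matching the VCF source format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO

import numpy as np
from cyvcf2 import VCF


class VcfParseError(RuntimeError):
    """Raised when the input VCF cannot be parsed."""


class ConfigurationError(ValueError):
    """Raised when sample roles or run configuration are inconsistent."""


@dataclass
class SampleCall:
    """One sample's call at one site.

    ``genotype`` is an unphased diploid call as a pair of allele indices,
    or ``None`` when the call is missing (``./.``) — distinct from
    homozygous-reference ``(0, 0)``.  ``ad_ref``/``ad_alt`` are read counts
    for the reference and the first alternate allele; ``ad_other`` collects
    depth on any further alternates of a multi-allelic record.  Strand-split
    counts are optional.
    """

    genotype: Optional[tuple[int, int]]
    ad_ref: int = 0
    ad_alt: int = 0
    ad_other: int = 0
    adf_ref: Optional[int] = None
    adf_alt: Optional[int] = None
    adr_ref: Optional[int] = None
    adr_alt: Optional[int] = None

    @property
    def depth(self) -> int:
        """Total read depth over all alleles."""
        return self.ad_ref + self.ad_alt + self.ad_other

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype == (0, 0)

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]

    @property
    def has_strand_counts(self) -> bool:
        return None not in (self.adf_ref, self.adf_alt, self.adr_ref, self.adr_alt)


@dataclass
class Variant:
    """One VCF site with a parent call and one or two bulk calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    parent: SampleCall
    bulks: tuple[SampleCall, ...]
    qual: Optional[float] = None
    mq: Optional[float] = None
    ann: Optional[str] = None  # raw SnpEff ANN INFO string, if present

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if len(self.bulks) not in (1, 2):
            raise ValueError("a variant carries 1 (one-bulk) or 2 (two-bulk) bulk calls")
        if not self.alts:
            raise ValueError("alts must be non-empty")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1


@dataclass
class GenomeInfo:
    """Chromosome layout plus optional genetic-map length.

    ``total_cm`` (total map length in centimorgans) is only needed for the
    optional multiple-testing correction.
    """

    chromosomes: tuple[tuple[str, int], ...]
    total_cm: Optional[float] = None

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def genome_size_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"chromosome {chrom!r} not in genome")


@dataclass(frozen=True)
class SampleRoles:
    """Explicit mapping of VCF sample names (or 0-based indices) to roles.

    Roles are never guessed from sample order: the caller states which
    sample is the parent and which are the bulks.
    """

    parent: str | int
    bulk1: str | int
    bulk2: Optional[str | int] = None

    @property
    def n_bulks(self) -> int:
        return 1 if self.bulk2 is None else 2

    def resolve(self, samples: Sequence[str]) -> tuple[int, ...]:
        """Return sample column indices (parent, bulk1[, bulk2])."""
        indices = []
        for role, key in (("parent", self.parent), ("bulk1", self.bulk1),
                          ("bulk2", self.bulk2)):
            if key is None:
                continue
            if isinstance(key, int):
                if not 0 <= key < len(samples):
                    raise ConfigurationError(
                        f"{role} index {key} out of range for {len(samples)} samples")
                indices.append(key)
            else:
                if key not in samples:
                    raise ConfigurationError(
                        f"{role} sample {key!r} not in VCF header samples {list(samples)}")
                indices.append(samples.index(key))
        if len(set(indices)) != len(indices):
            raise ConfigurationError("sample roles must name distinct samples")
        return tuple(indices)


def _int_or_zero(value) -> int:
    """cyvcf2 fills missing integer FORMAT values with negative sentinels."""
    v = int(value)
    return v if v >= 0 else 0


def _sample_call(gts, ad, adf, adr, col: int, n_alts: int) -> SampleCall:
    g = gts[col]
    genotype: Optional[tuple[int, int]]
    if g[0] < 0 or g[1] < 0:
        genotype = None
    else:
        genotype = (int(g[0]), int(g[1]))

    def row(mat):
        return None if mat is None else mat[col]

    ad_row, adf_row, adr_row = row(ad), row(adf), row(adr)
    if ad_row is None and adf_row is not None and adr_row is not None:
        # AD absent but strand-split depths present: reconstruct.
        ad_row = np.maximum(adf_row, 0) + np.maximum(adr_row, 0)

    if ad_row is None:
        ad_ref = ad_alt = ad_other = 0
    else:
        ad_ref = _int_or_zero(ad_row[0])
        ad_alt = _int_or_zero(ad_row[1]) if len(ad_row) > 1 else 0
        ad_other = sum(_int_or_zero(x) for x in ad_row[2:2 + max(0, n_alts - 1)])

    call = SampleCall(genotype=genotype, ad_ref=ad_ref, ad_alt=ad_alt, ad_other=ad_other)
    if adf_row is not None and adr_row is not None and len(adf_row) > 1:
        call.adf_ref = _int_or_zero(adf_row[0])
        call.adf_alt = _int_or_zero(adf_row[1])
        call.adr_ref = _int_or_zero(adr_row[0])
        call.adr_alt = _int_or_zero(adr_row[1])
    return call


def read_variants(vcf_path: str, roles: SampleRoles) -> Iterator[Variant]:
    """Stream :class:`Variant` records from a VCF file.

    Accepts plain or bgzipped VCF; no index required (full scan).  Records
    lacking AD for a role yield depth-0 calls, which downstream filters
    remove.  Multi-allelic records keep every alternate allele.

    Parameters
    ----------
    vcf_path:
        Path to a VCF 4.x file with GT (and normally AD) FORMAT fields.
    roles:
        Which sample is the parent and which are the bulk(s).
    """
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"cannot parse VCF {vcf_path!r}: {exc}") from exc
    cols = roles.resolve(vcf.samples)
    parent_col, bulk_cols = cols[0], cols[1:]

    def fmt(rec, key):
        try:
            return rec.format(key)
        except KeyError:  # FORMAT field not declared in this VCF's header
            return None

    for rec in vcf:
        if not rec.ALT:
            continue  # monomorphic record: nothing to index
        gts = rec.genotypes
        ad = fmt(rec, "AD")
        adf = fmt(rec, "ADF")
        adr = fmt(rec, "ADR")
        n_alts = len(rec.ALT)
        parent = _sample_call(gts, ad, adf, adr, parent_col, n_alts)
        bulks = tuple(_sample_call(gts, ad, adf, adr, c, n_alts) for c in bulk_cols)
        mq = rec.INFO.get("MQ")
        ann = rec.INFO.get("ANN")
        yield Variant(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alts=tuple(rec.ALT),
            parent=parent,
            bulks=bulks,
            qual=rec.QUAL,
            mq=float(mq) if mq is not None else None,
            ann=ann,
        )


def genome_from_vcf_header(vcf_path: str, total_cm: Optional[float] = None) -> Optional[GenomeInfo]:
    """Build :class:`GenomeInfo` from ##contig header lines, or None if absent."""
    vcf = VCF(str(vcf_path))
    names, lengths = vcf.seqnames, vcf.seqlens
    if not names or not lengths or len(names) != len(lengths):
        return None
    return GenomeInfo(chromosomes=tuple(zip(names, (int(l) for l in lengths))),
                      total_cm=total_cm)


def write_snpindex_table(records: Iterable, sink: TextIO, levels: Sequence[float] = ()) -> None:
    """Write per-variant SNP-index records as TSV.

    ``records`` are indexed variants (see :mod:`bsascan.bsa_stats`) carrying
    chrom, pos, ref, alt, per-bulk depth and SNP-index, delta in two-bulk
    mode, and per-level confidence bounds.  Floats are rendered with 4
    decimal places; one header line is always written, so an empty stream
    yields a header-only file.
    """
    records = iter(records)
    try:
        first = next(records)
    except StopIteration:
        first = None

    n_bulks = len(first.indices) if first is not None else 1
    cols = ["CHROM", "POS", "REF", "ALT"]
    for b in range(1, n_bulks + 1):
        cols += [f"BULK{b}_DEPTH", f"BULK{b}_SNP_INDEX"]
    if n_bulks == 2:
        cols.append("DELTA_SNP_INDEX")
    for lv in levels:
        tag = f"{lv:g}"
        cols += [f"CI{tag}_LOWER", f"CI{tag}_UPPER", f"SIG{tag}"]
    sink.write("\t".join(cols) + "\n")

    def emit(rec) -> None:
        fields = [rec.chrom, str(rec.pos), rec.ref, rec.alt]
        for d, ix in zip(rec.depths, rec.indices):
            fields += [str(d), f"{ix:.4f}"]
        if n_bulks == 2:
            fields.append(f"{rec.delta:.4f}")
        for lv in levels:
            lo, hi = rec.ci[lv]
            fields += [f"{lo:.4f}", f"{hi:.4f}", "1" if rec.flags.get(lv) else "0"]
        sink.write("\t".join(fields) + "\n")

    if first is not None:
        emit(first)
        for rec in records:
            emit(rec)
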