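"""End-to-end from-VCF analysis: filter, index, simulate, classify, report.

This is the library entry point behind the ``onebulk`` and ``twobulk``
commands; all outputs land in one directory together with a
machine-readable run log that records every parameter, the seed, and the
per-reason filter counts needed to reproduce the run exactly.
"""

from __future__ import annotations

import json
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import bsa_stats, filters, null_simulation, reporting, vcf_io
from .filters import FilterConfig
from .null_simulation import BulkDesign, CITable, CorrectionInput
from .vcf_io import GenomeInfo, SampleRoles


class PipelineError(RuntimeError):
    """Raised when a run cannot produce output (e.g. nothing passes filters)."""

    def __init__(self, message: str, filter_counts: Optional[Counter] = None):
        super().__init__(message)
        self.filter_counts = filter_counts or Counter()


@dataclass
class RunConfig:
    mode: str  # "one-bulk" | "two-bulk"
    vcf: str
    roles: SampleRoles
    designs: tuple[BulkDesign, ...]
    outdir: str
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    window_bp: int = 2_000_000
    step_bp: int = 100_000
    min_variants: int = 3
    levels: tuple[float, ...] = null_simulation.DEFAULT_LEVELS
    reps: int = null_simulation.DEFAULT_REPS
    seed: int = 0
    depth_cap: int = null_simulation.DEFAULT_DEPTH_CAP
    two_sided: bool = True
    correction: Optional[CorrectionInput] = None
    genome: Optional[GenomeInfo] = None

    def __post_init__(self) -> None:
        n_expected = 1 if self.mode == "one-bulk" else 2
        if len(self.designs) != n_expected:
            raise PipelineError(f"{self.mode} mode requires {n_expected} bulk design(s)")
        if self.roles.n_bulks != n_expected:
            raise PipelineError(f"{self.mode} mode requires {n_expected} bulk sample role(s)")


@dataclass
class RunResult:
    config: RunConfig
    genome: GenomeInfo
    indexed: list
    windows: list
    ci_table: CITable
    filter_counts: Counter
    levels_effective: tuple[float, ...]
    outputs: dict[str, str]


def _infer_genome(variants) -> GenomeInfo:
    # Fallback when the VCF header has no contig lengths: chromosome length
    # is taken as the last variant position seen on it.
    lengths: dict[str, int] = {}
    for v in variants:
        lengths[v.chrom] = max(lengths.get(v.chrom, 0), v.pos)
    return GenomeInfo(chromosomes=tuple(lengths.items()))


def run(config: RunConfig) -> RunResult:
    """Execute a full analysis and write the output file set."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    variants = list(vcf_io.read_variants(config.vcf, config.roles))
    verdicts = [filters.apply_filters(v, config.filter_config, config.mode)
                for v in variants]
    counts = filters.summarize_verdicts(verdicts)
    kept = [v for v, verdict in zip(variants, verdicts) if verdict.keep]
    if not kept:
        raise PipelineError(
            "no variants left after filtering; " + filters.format_filter_summary(counts),
            filter_counts=counts)

    genome = config.genome or vcf_io.genome_from_vcf_header(config.vcf) \
        or _infer_genome(kept)
    indexed = [bsa_stats.index_variant(v) for v in kept]

    if config.correction is not None:
        levels_effective = null_simulation.corrected_levels(config.levels, config.correction)
    else:
        levels_effective = tuple(sorted(config.levels))

    windows = list(bsa_stats.sliding_windows(
        indexed, config.window_bp, config.step_bp, config.min_variants, genome))

    # one simulation table serves both the per-variant test and window bands
    depth_keys = [v.depth_key for v in indexed]
    for w in windows:
        if not w.masked:
            d = tuple(max(1, int(round(x))) for x in w.mean_depth)
            depth_keys.append(d[0] if len(d) == 1 else d)
    designs = config.designs[0] if config.mode == "one-bulk" else tuple(config.designs)
    ci_table = null_simulation.build_ci_table(
        depth_keys, designs, levels=levels_effective, reps=config.reps,
        seed=config.seed, depth_cap=config.depth_cap, two_sided=config.two_sided)

    for v in indexed:
        null_simulation.classify(v, ci_table)
    null_simulation.attach_window_ci(windows, ci_table)

    outputs = {
        "snp_index": str(outdir / "snp_index.tsv"),
        "windows": str(outdir / "windows.tsv"),
        "ci_table": str(outdir / "ci_table.tsv"),
        "candidates": str(outdir / "candidates.tsv"),
        "plot_png": str(outdir / "scan.png"),
        "plot_svg": str(outdir / "scan.svg"),
        "log": str(outdir / "run_log.json"),
    }
    with open(outputs["snp_index"], "w") as fh:
        vcf_io.write_snpindex_table(indexed, fh, levels=levels_effective)
    with open(outputs["windows"], "w") as fh:
        bsa_stats.write_window_table(windows, fh, levels=levels_effective)
    with open(outputs["ci_table"], "w") as fh:
        ci_table.to_tsv(fh)
    with open(outputs["candidates"], "w") as fh:
        reporting.candidate_table(indexed, min(levels_effective), fh)
    reporting.plot_scan(indexed, windows, levels_effective,
                        outputs["plot_png"], mode=config.mode)
    reporting.plot_scan(indexed, windows, levels_effective,
                        outputs["plot_svg"], mode=config.mode)

    log = {
        "mode": config.mode,
        "vcf": str(config.vcf),
        "roles": {"parent": config.roles.parent, "bulk1": config.roles.bulk1,
                  "bulk2": config.roles.bulk2},
        "designs": [{"n_individuals": d.n_individuals, "generation": d.generation}
                    for d in config.designs],
        "filter_config": vars(config.filter_config),
        "window_bp": config.window_bp,
        "step_bp": config.step_bp,
        "min_variants": config.min_variants,
        "levels": list(config.levels),
        "levels_effective": list(levels_effective),
        "reps": config.reps,
        "seed": config.seed,
        "depth_cap": config.depth_cap,
        "two_sided": config.two_sided,
        "correction": vars(config.correction) if config.correction else None,
        "filter_counts": dict(counts),
        "n_variants_kept": len(indexed),
        "runtime_s": round(time.monotonic() - t0, 3),
    }
    with open(outputs["log"], "w") as fh:
        json.dump(log, fh, indent=2, default=str)
        fh.write("\n")

    return RunResult(config=config, genome=genome, indexed=indexed,
                     windows=windows, ci_table=ci_table, filter_counts=counts,
                     levels_effective=levels_effective, outputs=outputs)
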