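"""Genome-scan plots, candidate tables, and SnpEff annotation display.

SnpEff is never executed here; when the input VCF already carries its ANN
INFO field the annotations are parsed and shown alongside candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bsa_stats import IndexedVariant, WindowRecord

#: Plot styling, overridable by callers.
STYLE = {
    "point_color": "0.55",
    "point_size": 4,
    "line_color": "#c0392b",
    "band_color": "#2980b9",
    "band_alpha": {0: 0.25, 1: 0.15},  # per-level opacity rank
}


@dataclass
class Annotation:
    allele: str
    effect: str
    impact: str
    gene: str


def parse_ann(ann_string: Optional[str]) -> list[Annotation]:
    """Parse a SnpEff ANN INFO string.

    Entries are comma-separated; sub-fields pipe-delimited, of which only
    the first four (allele, effect, impact, gene name) are kept.  Malformed
    entries are skipped with a warning; a missing string yields [].
    """
    if not ann_string:
        return []
    out = []
    for entry in ann_string.split(","):
        parts = entry.split("|")
        if len(parts) < 4:
            warnings.warn(f"skipping malformed ANN entry: {entry!r}")
            continue
        out.append(Annotation(allele=parts[0], effect=parts[1],
                              impact=parts[2], gene=parts[3]))
    return out


class EmptyChromosomeError(ValueError):
    pass


def plot_scan(
    indexed_variants: Sequence[IndexedVariant],
    windows: Sequence[WindowRecord],
    levels: Sequence[float],
    output_path: str,
    mode: str = "one-bulk",
) -> None:
    """Write the per-chromosome genome-scan figure.

    One panel per chromosome: per-variant statistic as points, sliding-
    window means as a line (gaps at masked windows, never interpolated),
    and shaded null confidence bands per level.  x is Mb; y is the
    SNP-index in [0, 1] (one-bulk) or the delta SNP-index in [-1, 1]
    (two-bulk, with a zero reference line).  Output format follows the file
    suffix (png, svg, pdf).
    """
    if not indexed_variants:
        raise EmptyChromosomeError("no variants to plot on any chromosome")
    chroms = list(dict.fromkeys(w.chrom for w in windows)) or \
        list(dict.fromkeys(v.chrom for v in indexed_variants))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.4 * len(chroms)),
                             squeeze=False, sharey=True)
    levels = sorted(levels)
    for ax, chrom in zip(axes.ravel(), chroms):
        vs = [v for v in indexed_variants if v.chrom == chrom]
        ws = [w for w in windows if w.chrom == chrom]
        ax.scatter([v.pos / 1e6 for v in vs], [v.statistic for v in vs],
                   s=STYLE["point_size"], color=STYLE["point_color"],
                   linewidths=0, rasterized=True)
        centers = np.array([w.center / 1e6 for w in ws])
        stats = np.array([np.nan if w.masked else w.statistic for w in ws], dtype=float)
        ax.plot(centers, stats, color=STYLE["line_color"], lw=1.5)
        for rank, lv in enumerate(levels):
            lo = np.array([w.ci.get(lv, (np.nan, np.nan))[0] if not w.masked else np.nan
                           for w in ws], dtype=float)
            hi = np.array([w.ci.get(lv, (np.nan, np.nan))[1] if not w.masked else np.nan
                           for w in ws], dtype=float)
            ax.fill_between(centers, lo, hi, color=STYLE["band_color"],
                            alpha=STYLE["band_alpha"].get(rank, 0.1),
                            linewidth=0, label=f"{lv:g} CI")
        if mode == "two-bulk":
            ax.axhline(0.0, color="k", lw=0.6)
            ax.set_ylim(-1.0, 1.0)
            ax.set_ylabel("ΔSNP-index")
        else:
            ax.set_ylim(0.0, 1.0)
            ax.set_ylabel("SNP-index")
        ax.set_title(chrom, loc="left", fontsize=10)
        ax.set_xlabel("position (Mb)")
    axes.ravel()[0].legend(loc="upper right", fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)


def candidate_table(classified_variants: Sequence[IndexedVariant], level: float,
                    sink) -> int:
    """Write flagged variants at ``level`` as a TSV; returns the row count.

    Only variants flagged at the requested level appear.  Annotation
    columns are included when any flagged variant carries a parsed ANN
    field.  Rows are sorted by (chrom, pos).
    """
    flagged = sorted((v for v in classified_variants if v.flags.get(level)),
                     key=lambda v: (v.chrom, v.pos))
    any_ann = any(parse_ann(v.ann) for v in flagged)
    two_bulk = bool(flagged) and len(flagged[0].depths) == 2
    cols = ["CHROM", "POS", "REF", "ALT"]
    n_bulks = len(flagged[0].depths) if flagged else 1
    for b in range(1, n_bulks + 1):
        cols += [f"BULK{b}_DEPTH", f"BULK{b}_SNP_INDEX"]
    if two_bulk:
        cols.append("DELTA_SNP_INDEX")
    cols.append("FLAGGED_LEVELS")
    if any_ann:
        cols += ["GENE", "EFFECT", "IMPACT"]
    sink.write("\t".join(cols) + "\n")
    for v in flagged:
        fields = [v.chrom, str(v.pos), v.ref, v.alt]
        for d, ix in zip(v.depths, v.indices):
            fields += [str(d), f"{ix:.4f}"]
        if two_bulk:
            fields.append(f"{v.delta:.4f}")
        fields.append(",".join(f"{lv:g}" for lv in sorted(v.flags) if v.flags[lv]))
        if any_ann:
            anns = parse_ann(v.ann)
            if anns:
                fields += [anns[0].gene, anns[0].effect, anns[0].impact]
            else:
                fields += ["NA", "NA", "NA"]
        sink.write("\t".join(fields) + "\n")
    return len(flagged)
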