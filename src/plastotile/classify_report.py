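"""Genomic-context classification of differential segments and the summary
arithmetic of the pipeline's report tables.

Classification precedence is conservative for noncoding calling: a segment
overlapping any ORF (exonic) nucleotide is *genic*; otherwise a segment
fully or partly inside an intron is *intronic*; everything else is
*intergenic*.  Noncoding = intergenic + intronic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import (
    Annotation,
    circular_distance,
    interval_length,
    intervals_overlap_length,
)

__all__ = [
    "SegmentClass",
    "SummaryReport",
    "classify_segment",
    "noncoding_summary",
    "summarize_counts",
]


@dataclass(frozen=True)
class SegmentClass:
    start: int
    end: int
    label: str      # intergenic | intronic | genic
    feature: str    # containing/nearest feature name


@dataclass
class SummaryReport:
    """Tallies of differential entities per class and per ZT."""

    class_counts: dict          # label -> count
    noncoding_total: int
    total: int
    per_zt: pd.DataFrame | None = None      # ZT × direction counts
    per_zt_fraction: pd.Series | None = None
    n_differential: int | None = None
    total_genes: int | None = None
    percent_of_orfs: int | None = None

    def to_text(self) -> str:
        lines = []
        if self.total:
            lines.append(
                f"{self.total} differential segments: "
                + ", ".join(f"{v} {k}" for k, v in self.class_counts.items())
            )
            lines.append(
                f"noncoding (intergenic + intronic): {self.noncoding_total} "
                f"of {self.total}"
            )
        if self.percent_of_orfs is not None:
            lines.append(
                f"{self.n_differential} of {self.total_genes} genes "
                f"differential in ≥1 ZT ({self.percent_of_orfs}% of ORFs)"
            )
        if self.per_zt is not None and len(self.per_zt):
            lines.append("per-ZT counts:")
            lines.append(self.per_zt.to_string())
        return "\n".join(lines)


def classify_segment(
    segment: tuple[int, int], annotation: Annotation
) -> SegmentClass:
    """Classify one interval by genomic context (genic > intronic > intergenic)."""
    L = annotation.genome_length
    start, end = segment
    for gene in annotation.genes:
        for (es, ee) in annotation.exonic_intervals(gene.name):
            if intervals_overlap_length((start, end), (es, ee), L) > 0:
                return SegmentClass(start, end, "genic", gene.name)
    for intron in annotation.introns:
        if intervals_overlap_length((start, end),
                                    (intron.start, intron.end), L) > 0:
            return SegmentClass(start, end, "intronic", intron.parent)
    # intergenic: report the nearest gene by circular boundary distance
    nearest, best = "", None
    mid = (start + interval_length(start, end, L) // 2) % L
    for gene in annotation.genes:
        d = min(circular_distance(mid, gene.start, L),
                circular_distance(mid, gene.end % L, L))
        if best is None or d < best:
            nearest, best = gene.name, d
    return SegmentClass(start, end, "intergenic", nearest)


def noncoding_summary(
    classified: list[SegmentClass],
    zt_directions: list[tuple[int, str]] | None = None,
) -> SummaryReport:
    """Tally classified differential segments; noncoding = intergenic + intronic.

    ``zt_directions`` optionally aligns a (ZT, direction) pair with each
    segment to build the per-ZT up/down regulation matrix.
    """
    counts = {"intergenic": 0, "intronic": 0, "genic": 0}
    for c in classified:
        counts[c.label] += 1
    per_zt = None
    per_zt_fraction = None
    if zt_directions is not None:
        df = pd.DataFrame(zt_directions, columns=["zt", "direction"])
        per_zt = df.value_counts(["zt", "direction"]).unstack(fill_value=0)
        totals = df.value_counts("zt")
        per_zt_fraction = (totals / len(df)).sort_index() if len(df) else totals
    return SummaryReport(
        class_counts=counts,
        noncoding_total=counts["intergenic"] + counts["intronic"],
        total=sum(counts.values()),
        per_zt=per_zt,
        per_zt_fraction=per_zt_fraction,
    )


def summarize_counts(calls: pd.DataFrame, total_orfs: int) -> SummaryReport:
    """Summary arithmetic over a gene-call matrix (genes × ZT of up/down/ns).

    Reports genes differential in at least one ZT, that count as a percent
    of all ORFs (rounded to the nearest integer), per-ZT counts, and each
    ZT's share of the differential set.
    """
    diff_mask = calls != "ns"
    n_diff = int(diff_mask.any(axis=1).sum())
    if total_orfs < n_diff:
        raise ValueError(
            f"total ORFs ({total_orfs}) below differential count ({n_diff})"
        )
    per_zt = diff_mask.sum(axis=0)
    rows = []
    for zt in calls.columns:
        col = calls[zt]
        rows.append(dict(zt=zt, up=int((col == "up").sum()),
                         down=int((col == "down").sum())))
    per_zt_matrix = pd.DataFrame(rows).set_index("zt")
    frac = per_zt / n_diff if n_diff else per_zt.astype(float)
    return SummaryReport(
        class_counts={}, noncoding_total=0, total=0,
        per_zt=per_zt_matrix, per_zt_fraction=frac,
        n_differential=n_diff, total_genes=total_orfs,
        percent_of_orfs=int(round(100.0 * n_diff / total_orfs)),
    )
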