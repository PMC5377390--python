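"""Plots for smoothed transcription tracks and gene-call matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_formats import Annotation
from .segmentation import Segment, SmoothedTrack

ZT_COLORS = {0: "#e377c2", 7: "#bcbd22", 14: "#ff7f0e", 19: "#1f77b4"}


def plot_tracks(
    tracks: dict[tuple[str, int], SmoothedTrack],
    annotation: Annotation | None = None,
    threshold: float | None = None,
    region: tuple[int, int] | None = None,
    ax=None,
):
    """Overlay smoothed log-intensity tracks, one line per condition.

    Solid lines are wild type, dashed the overexpressor; ZT sets the colour.
    Optionally draws the detection threshold and gene boxes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    for (genotype, zt), track in sorted(tracks.items()):
        style = "-" if genotype == "WT" else "--"
        c = track.centers
        v = track.values
        if region is not None:
            m = (c >= region[0]) & (c < region[1])
            c, v = c[m], v[m]
        ax.plot(c, v, style, color=ZT_COLORS.get(zt, "gray"), lw=0.8,
                label=f"{genotype} ZT{zt}")
    if threshold is not None:
        ax.axhline(threshold, color="k", ls=":", lw=0.8, label="threshold")
    if annotation is not None:
        y0 = ax.get_ylim()[0]
        for gene in annotation.genes:
            if region is not None and (gene.end < region[0] or gene.start > region[1]):
                continue
            ax.annotate("", xy=(gene.end, y0), xytext=(gene.start, y0),
                        arrowprops=dict(arrowstyle="-|>", color="0.3"))
    ax.set_xlabel("genome position (nt)")
    ax.set_ylabel("smoothed log intensity")
    ax.legend(fontsize=6, ncol=4)
    return ax


def plot_gene_calls(calls, ax=None):
    """Gene × ZT regulation matrix: green = up, red = down, white = ns."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, max(3, 0.18 * len(calls))))
    code = calls.map(lambda v: {"ns": 0, "up": 1, "down": -1}.get(v, 0)).astype(float)
    ax.imshow(code.to_numpy(), cmap="RdYlGn", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(calls.columns)),
                  [f"ZT{z}" for z in calls.columns])
    ax.set_yticks(range(len(calls.index)), calls.index, fontsize=5)
    ax.set_title("differential calls (CRY2-OX vs WT)")
    return ax


def plot_segment_coverage(segments: list[Segment], genome_length: int, ax=None):
    """Horizontal bars of detected segments along the circle (unwrapped)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 1.5))
    for seg in segments:
        spans = [(seg.start, seg.end)] if seg.start <= seg.end else [
            (seg.start, genome_length), (0, seg.end)
        ]
        for (s, e) in spans:
            ax.axvspan(s, e, color="tab:blue", alpha=0.4)
    ax.set_xlim(0, genome_length)
    ax.set_yticks([])
    ax.set_xlabel("genome position (nt)")
    return ax
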