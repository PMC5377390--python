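"""Transcript 5′-end mapping and PEP / NEP class-Ib promoter motif scanning.

The 5′ boundary of the transcribed segment overlapping a gene's start codon
is taken as the apparent transcription start (TSS) for that gene in that
condition.  Condition-to-condition differences of the TSS-to-ATG distance
are reported as 5′ shifts (positive = closer to the ATG, i.e. a shorter
transcript); the pipeline reports boundaries, not mechanism — an apparent
shift can equally reflect 5′ processing.

Promoter scans anchor on a TSS position and search upstream sequence in
transcript orientation:

* PEP (σ70-type): a ≤1-mismatch TATAAT whose last base lies 4–12 nt upstream
  of the TSS plus a ≤1-mismatch TTGACA separated from the −10 box start by a
  15–21-nt spacer;
* NEP class Ib: an exact YRTa core (Y∈{C,T}, R∈{A,G}) with its final A at
  TSS−1 or TSS+1, plus an exact GAA box starting 10–40 nt upstream of the
  core start.

All positions are circular; scans are invariant under genome rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Annotation, CircularGenome, Gene, interval_contains
from .probe_design import reverse_complement
from .segmentation import Segment

__all__ = [
    "TSSRecord",
    "TSSShift",
    "PromoterHit",
    "map_tss",
    "detect_tss_shift",
    "scan_pep",
    "scan_nep_class1b",
]


@dataclass(frozen=True)
class TSSRecord:
    gene: str
    condition: tuple[str, int]
    tss_position: int       # genome coordinate of the segment 5' boundary
    distance_to_atg: int    # nt upstream of the start codon (≥ 0 = upstream)
    strand: str = "+"


@dataclass(frozen=True)
class TSSShift:
    gene: str
    condition_a: tuple[str, int]
    condition_b: tuple[str, int]
    shift: int              # positive = condition_b 5' end closer to the ATG
    significant: bool
    shorter_condition: tuple[str, int] | None


@dataclass(frozen=True)
class PromoterHit:
    type: str               # PEP | NEP_Ib
    tss: int
    strand: str
    boxes: dict = field(hash=False)        # name -> (genome start of box, matched seq)
    mismatches: int = 0


# ---------------------------------------------------------------------------
# TSS mapping
# ---------------------------------------------------------------------------

def map_tss(
    segments: list[Segment],
    annotation: Annotation,
    condition: tuple[str, int] | None = None,
) -> list[TSSRecord]:
    """Apparent TSS per expressed gene: the 5′ boundary (in gene orientation)
    of the segment overlapping the gene's start codon.  Genes with no
    overlapping segment are omitted."""
    L = annotation.genome_length
    records = []
    for gene in annotation.genes:
        atg = gene.atg_position()
        for seg in segments:
            if interval_contains(seg.start, seg.end, atg, L):
                if gene.strand == "+":
                    tss = seg.start
                    dist = (atg - seg.start) % L
                else:
                    tss = seg.end  # exclusive bound = 5' side on the minus strand
                    dist = (seg.end - atg) % L
                records.append(
                    TSSRecord(gene=gene.name,
                              condition=condition or seg.condition or ("", -1),
                              tss_position=tss, distance_to_atg=int(dist),
                              strand=gene.strand)
                )
                break
    return records


def detect_tss_shift(
    records: list[TSSRecord], min_shift: int = 25
) -> list[TSSShift]:
    """Pairwise 5′-boundary shifts of one gene across conditions.

    For every ordered condition pair (a, b) with a before b in the input,
    shift = distance(a) − distance(b); positive means the transcript is
    shorter in b.  Shifts of at least ``min_shift`` (default 25 nt = 5 ×
    step, the resolution of the join rules) are flagged."""
    by_gene: dict[str, list[TSSRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)
    shifts = []
    for gene, recs in by_gene.items():
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                delta = a.distance_to_atg - b.distance_to_atg
                flagged = abs(delta) >= min_shift
                shorter = None
                if delta > 0:
                    shorter = b.condition
                elif delta < 0:
                    shorter = a.condition
                shifts.append(
                    TSSShift(gene=gene, condition_a=a.condition,
                             condition_b=b.condition, shift=int(delta),
                             significant=flagged,
                             shorter_condition=shorter if flagged else None)
                )
    return shifts


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _upstream_coord(tss: int, strand: str, offset: int, L: int) -> int:
    """Genome coordinate of the base ``offset`` nt upstream of the TSS."""
    return (tss - offset) % L if strand == "+" else (tss + offset - 1) % L


def _oriented_window(
    genome: CircularGenome, tss: int, strand: str, upstream: int, downstream: int
) -> str:
    """Sequence from ``upstream`` nt before to ``downstream`` nt after the
    TSS, in transcript orientation; index ``upstream`` is the TSS base."""
    L = genome.length
    if strand == "+":
        return genome.fetch((tss - upstream) % L, (tss + downstream) % L)
    seq = genome.fetch((tss - downstream) % L, (tss + upstream) % L)
    return reverse_complement(seq)


def _mismatches(seq: str, motif: str) -> int:
    return sum(1 for s, m in zip(seq, motif) if s != m)


def scan_pep(
    genome: CircularGenome,
    tss: int,
    strand: str = "+",
    window: int = 100,
    max_mismatch: int = 1,
    gap_range: tuple[int, int] = (4, 12),
    spacer_range: tuple[int, int] = (15, 21),
) -> list[PromoterHit]:
    """Scan for σ70-type PEP promoters upstream of a TSS.

    Reports every (−35, −10) pair where the TATAAT-like box ends
    ``gap_range`` nt upstream of the TSS, the TTGACA-like box start is
    separated from the −10 start by ``spacer_range`` nt, and each box has at
    most ``max_mismatch`` mismatches.
    """
    L = genome.length
    up = _oriented_window(genome, tss, strand, window, 0)
    # up[k] is the base (window - k) nt upstream of the TSS
    def box_at(first_up: int, length: int) -> str:
        i = window - first_up
        return up[i : i + length]

    hits = []
    for gap in range(gap_range[0], gap_range[1] + 1):
        first10 = gap + len("TATAAT") - 1
        seq10 = box_at(first10, 6)
        if len(seq10) < 6 or _mismatches(seq10, "TATAAT") > max_mismatch:
            continue
        for spacer in range(spacer_range[0], spacer_range[1] + 1):
            first35 = first10 + spacer + len("TTGACA")
            if first35 > window:
                continue
            seq35 = box_at(first35, 6)
            if len(seq35) < 6 or _mismatches(seq35, "TTGACA") > max_mismatch:
                continue
            mm = _mismatches(seq10, "TATAAT") + _mismatches(seq35, "TTGACA")
            hits.append(
                PromoterHit(
                    type="PEP", tss=tss, strand=strand,
                    boxes={
                        "minus10": (_upstream_coord(tss, strand, first10, L), seq10),
                        "minus35": (_upstream_coord(tss, strand, first35, L), seq35),
                    },
                    mismatches=mm,
                )
            )
    return hits


def _is_yrta(seq: str) -> bool:
    return (len(seq) == 4 and seq[0] in "CT" and seq[1] in "AG"
            and seq[2] == "T" and seq[3] == "A")


def scan_nep_class1b(
    genome: CircularGenome,
    tss: int,
    strand: str = "+",
    window: int = 100,
    gaa_range: tuple[int, int] = (10, 40),
    core_only: bool = False,
) -> list[PromoterHit]:
    """Scan for NEP class-Ib promoters: a YRTa core with its final A at
    TSS−1 or TSS+1 plus an exact upstream GAA box.

    The GAA box must start ``gaa_range`` nt upstream of the YRTa start
    (start-to-start distance).  ``core_only`` reports YRTa cores without the
    GAA requirement (class-Ia-style scan).
    """
    L = genome.length
    up = _oriented_window(genome, tss, strand, window, 2)

    hits = []
    for last_a_off in (+1, -1):  # final A at TSS-1 or TSS+1 (offsets upstream)
        # offset (upstream) of the core's first base
        first_core = 3 + last_a_off if last_a_off == 1 else 3 - 1
        first_core = last_a_off + 3
        core_i = window - first_core
        core = up[core_i : core_i + 4]
        if not _is_yrta(core):
            continue
        core_start = _upstream_coord(tss, strand, first_core, L)
        if core_only:
            hits.append(
                PromoterHit(type="NEP_Ia", tss=tss, strand=strand,
                            boxes={"yrta": (core_start, core)})
            )
            continue
        for d in range(gaa_range[0], gaa_range[1] + 1):
            first_gaa = first_core + d
            if first_gaa > window:
                continue
            i = window - first_gaa
            if up[i : i + 3] == "GAA":
                hits.append(
                    PromoterHit(
                        type="NEP_Ib", tss=tss, strand=strand,
                        boxes={
                            "yrta": (core_start, core),
                            "gaa": (_upstream_coord(tss, strand, first_gaa, L), "GAA"),
                        },
                    )
                )
    return hits
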