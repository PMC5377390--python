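"""End-to-end orchestration of the tiling-array pipeline, plus recovery
scoring of pipeline output against a simulation's ground truth.

The stage order is: simulate (or load) → GC normalization → quantile
normalization → detection thresholds and replicate QC → pseudomedian
smoothing and segment assembly per (genotype, ZT) → windowed rank-sum
differential per ZT → gene calls → TSS mapping / promoter scans →
classification and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Annotation, CircularGenome, interval_length, unwrap_interval
from .probe_design import ProbeSet, add_negative_controls, mark_replicated, tile_probes
from .normalization import (
    DetectionThreshold,
    IntensityMatrix,
    QCReport,
    average_replicates,
    condition_thresholds,
    gc_normalize,
    qc_replicates,
    quantile_normalize,
)
from .segmentation import Segment, SmoothedTrack, assemble_segments, call_expressed, smooth_track
from .differential import DifferentialRegion, GeneCallMatrix, differential_regions, gene_calls, window_wilcoxon
from .synthetic_data import (
    GENOTYPES,
    ZTS,
    SimConfig,
    TruthTable,
    make_toy_plastome,
    simulate_intensities,
)
from .tss_promoter import TSSRecord, map_tss

__all__ = [
    "SimulatedDataset",
    "PipelineResult",
    "simulate_dataset",
    "normalize_matrix",
    "segment_conditions",
    "differential_by_zt",
    "run_pipeline",
    "covered_fraction",
    "segmentation_recovery",
    "differential_recovery",
]

DEFAULT_BANDWIDTH = 150.0
DEFAULT_ALPHA = 0.05
DEFAULT_SIM_SEED = 10  # the package's reference simulation


@dataclass
class SimulatedDataset:
    genome: CircularGenome
    annotation: Annotation
    truth: TruthTable
    probes: ProbeSet
    raw: IntensityMatrix


@dataclass
class PipelineResult:
    normalized: IntensityMatrix
    thresholds: dict[tuple[str, int], DetectionThreshold]
    qc: QCReport
    tracks: dict[tuple[str, int], SmoothedTrack]
    segments: dict[tuple[str, int], list[Segment]]
    regions: dict[int, list[DifferentialRegion]]
    calls: GeneCallMatrix
    tss: dict[tuple[str, int], list[TSSRecord]] = field(default_factory=dict)


def simulate_dataset(config: SimConfig, seed: int) -> SimulatedDataset:
    """Toy plastome + tiled probes + 54 negative controls + 24-array matrix."""
    ss = np.random.SeedSequence(seed)
    s_genome, s_nc, s_dup, s_int = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    genome, annotation, truth = make_toy_plastome(config, seed=s_genome)
    probes = tile_probes(genome)
    probes = add_negative_controls(probes, 54, genome, seed=s_nc)
    probes = mark_replicated(probes, 0.67, seed=s_dup)
    raw = simulate_intensities(probes, annotation, truth, config, seed=s_int)
    return SimulatedDataset(genome, annotation, truth, probes, raw)


def normalize_matrix(
    raw: IntensityMatrix, probes: ProbeSet
) -> tuple[IntensityMatrix, dict[tuple[str, int], DetectionThreshold], QCReport]:
    gc = pd.Series(probes.table["gc"].to_numpy(), index=probes.table["id"])
    nc = pd.Series(probes.table["is_nc"].to_numpy(), index=probes.table["id"])
    norm = quantile_normalize(gc_normalize(raw, gc, nc))
    thresholds = condition_thresholds(norm, nc, pool="global")
    # replicate QC belongs to the hybridizations themselves, pre-normalization
    qc = qc_replicates(raw, nc_flags=nc)
    return norm, thresholds, qc


def segment_conditions(
    norm: IntensityMatrix,
    probes: ProbeSet,
    thresholds: dict[tuple[str, int], DetectionThreshold],
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> tuple[dict[tuple[str, int], SmoothedTrack], dict[tuple[str, int], list[Segment]]]:
    """Replicate-averaged smoothing and segment assembly per condition."""
    centers = probes.centers()
    order = np.argsort(centers)
    centers = centers[order]
    genomic_ids = probes.genomic["id"].to_numpy()[order]
    pooled = average_replicates(norm)
    tracks, segments = {}, {}
    for cond in norm.conditions():
        g, zt = cond
        vals = pooled[f"{g}_ZT{zt}"].loc[genomic_ids].to_numpy()
        track = smooth_track(vals, centers, probes.genome_length, bandwidth,
                             condition=cond)
        flags = call_expressed(track, thresholds[cond])
        segs = assemble_segments(
            flags, centers, probes.step, probes.genome_length,
            probe_length=probes.probe_length, levels=track.values,
            condition=cond,
        )
        tracks[cond], segments[cond] = track, segs
    return tracks, segments


DEFAULT_MIN_EFFECT = 0.2  # ln scale (≈ 0.29 log2): fold-change floor for regions


def differential_by_zt(
    norm: IntensityMatrix,
    probes: ProbeSet,
    bandwidth: float = DEFAULT_BANDWIDTH,
    alpha: float = DEFAULT_ALPHA,
    zts=ZTS,
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> dict[int, list[DifferentialRegion]]:
    """Windowed CRY2-OX vs WT rank-sum comparison, one region set per ZT.

    The pipeline driver pairs the p < alpha rule with a modest fold-change
    floor on the pseudomedian effect, the usual guard against small
    array-level normalization artifacts.
    """
    centers = probes.centers()
    order = np.argsort(centers)
    centers = centers[order]
    genomic_ids = probes.genomic["id"].to_numpy()[order]
    logv = norm.log_values()
    out: dict[int, list[DifferentialRegion]] = {}
    for zt in zts:
        cols_a = norm.condition_columns("CRY2OX", zt)
        cols_b = norm.condition_columns("WT", zt)
        if not cols_a or not cols_b:
            continue
        mat_a = logv[cols_a].loc[genomic_ids].to_numpy()
        mat_b = logv[cols_b].loc[genomic_ids].to_numpy()
        stats_df = window_wilcoxon(mat_a, mat_b, centers, probes.genome_length,
                                   bandwidth, zt=zt)
        out[zt] = differential_regions(
            stats_df, centers, probes.step, probes.genome_length, zt,
            alpha=alpha, probe_length=probes.probe_length,
            min_effect=min_effect,
        )
    return out


def run_pipeline(
    dataset: SimulatedDataset,
    bandwidth: float = DEFAULT_BANDWIDTH,
    alpha: float = DEFAULT_ALPHA,
    min_coverage: float = 0.5,
) -> PipelineResult:
    """Full analysis of one dataset (simulated or loaded)."""
    norm, thresholds, qc = normalize_matrix(dataset.raw, dataset.probes)
    tracks, segments = segment_conditions(norm, dataset.probes, thresholds,
                                          bandwidth)
    regions = differential_by_zt(norm, dataset.probes, bandwidth, alpha)
    calls = gene_calls(regions, dataset.annotation, min_coverage)
    tss = {
        cond: map_tss(segs, dataset.annotation, condition=cond)
        for cond, segs in segments.items()
    }
    return PipelineResult(normalized=norm, thresholds=thresholds, qc=qc,
                          tracks=tracks, segments=segments, regions=regions,
                          calls=calls, tss=tss)


# ---------------------------------------------------------------------------
# recovery scoring against the truth table
# ---------------------------------------------------------------------------

def _coverage_mask(intervals, L: int) -> np.ndarray:
    mask = np.zeros(L, dtype=bool)
    for (s, e) in intervals:
        for (a, b) in unwrap_interval(s % L, e % L, L):
            mask[a:b] = True
    return mask


def covered_fraction(target_intervals, covering_intervals, L: int) -> float:
    """Fraction of the target nucleotides covered by the covering intervals."""
    target = _coverage_mask(target_intervals, L)
    cover = _coverage_mask(covering_intervals, L)
    denom = target.sum()
    return float((target & cover).sum() / denom) if denom else float("nan")


def segmentation_recovery(
    truth: TruthTable, segments: dict[tuple[str, int], list[Segment]]
) -> pd.DataFrame:
    """Per-condition sensitivity/specificity of segment detection.

    sensitivity = fraction of truly transcribed nucleotides inside detected
    segments; background_coverage = fraction of true background nucleotides
    inside detected segments.  Both are also meaningful averaged over the
    eight conditions.
    """
    L = truth.genome_length
    rows = []
    for (g, zt), segs in segments.items():
        true_iv = truth.transcribed_intervals(g, zt)
        true_mask = _coverage_mask(true_iv, L)
        seg_mask = _coverage_mask([(s.start, s.end) for s in segs], L)
        sens = float((true_mask & seg_mask).sum() / true_mask.sum())
        bg = ~true_mask
        fp = float((bg & seg_mask).sum() / bg.sum())
        rows.append(dict(genotype=g, zt=zt, sensitivity=sens,
                         background_coverage=fp))
    return pd.DataFrame(rows)


def differential_recovery(
    truth: TruthTable, annotation: Annotation, calls: GeneCallMatrix
) -> dict:
    """Score gene-level calls against the injected unit effects.

    An injected (unit, ZT, direction) counts as recovered when every gene of
    the unit is called in that direction at that ZT; the false-call rate is
    the fraction of all non-ns calls at (gene, ZT) pairs that were not
    injected (ncRNA effects inside or between genes are not gene truths).
    Genes of a 5′-truncated unit genuinely differ between genotypes at the
    truncated (ZT); calls there are allowed without being required.
    """
    unit_genes: dict[str, list[str]] = {}
    for g in annotation.genes:
        unit_genes.setdefault(g.name.split("g")[0], []).append(g.name)

    expected: dict[tuple[str, int], str] = {}
    for eff in truth.de_effects:
        for zt in eff.zts:
            for gene in unit_genes.get(eff.target, []):
                expected[(gene, zt)] = eff.direction

    allowed: dict[tuple[str, int], str] = {}
    for sh in truth.tss_shifts:
        direction = "up" if sh.genotype == "WT" else "down"
        for gene in unit_genes.get(sh.unit, []):
            allowed[(gene, sh.zt)] = direction

    n_expected = len(expected)
    n_recovered = sum(
        1 for (gene, zt), d in expected.items()
        if zt in calls.calls.columns and calls.calls.loc[gene, zt] == d
    )
    n_calls = 0
    n_false = 0
    for gene in calls.calls.index:
        for zt in calls.calls.columns:
            c = calls.calls.loc[gene, zt]
            if c == "ns":
                continue
            n_calls += 1
            if expected.get((gene, zt)) != c and allowed.get((gene, zt)) != c:
                n_false += 1
    return dict(
        n_expected=n_expected,
        n_recovered=n_recovered,
        sensitivity=n_recovered / n_expected if n_expected else float("nan"),
        n_calls=n_calls,
        n_false=n_false,
        false_call_fraction=n_false / n_calls if n_calls else 0.0,
    )
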