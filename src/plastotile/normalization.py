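"""Probe-intensity normalization, background thresholds and replicate QC.

Processing order follows the array-analysis convention adopted throughout
the package: per-array GC-bin normalization first, then cross-array quantile
normalization, then per-array detection thresholds from the negative
controls (mean + 2 × sample sd).  All normalization acts on natural-log
intensities — the noise model is multiplicative — and thresholds live on the
same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import write_tsv

__all__ = [
    "IntensityMatrix",
    "DetectionThreshold",
    "QCReport",
    "gc_normalize",
    "quantile_normalize",
    "detection_threshold",
    "condition_thresholds",
    "qc_replicates",
    "average_replicates",
    "parse_array_key",
]


def parse_array_key(key: str) -> tuple[str, int, int]:
    """``"WT_ZT14_R2" -> ("WT", 14, 2)``."""
    genotype, zt, rep = key.split("_")
    return genotype, int(zt[2:]), int(rep[1:])


@dataclass
class IntensityMatrix:
    """Probe × array table of strictly positive intensities.

    Columns are named ``GENOTYPE_ZTt_Rr``; the index holds probe ids.  The
    ``stage`` tag tracks where the matrix is in the normalization chain.
    """

    values: pd.DataFrame
    stage: str = "raw"  # raw | gc_normalized | quantile_normalized
    duplicate_spots: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("intensity matrix contains missing cells")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive")

    @property
    def arrays(self) -> list[str]:
        return list(self.values.columns)

    def log_values(self) -> pd.DataFrame:
        return np.log(self.values)

    def conditions(self) -> list[tuple[str, int]]:
        seen: list[tuple[str, int]] = []
        for key in self.arrays:
            g, zt, _ = parse_array_key(key)
            if (g, zt) not in seen:
                seen.append((g, zt))
        return seen

    def condition_columns(self, genotype: str, zt: int) -> list[str]:
        return [
            k for k in self.arrays
            if parse_array_key(k)[0] == genotype and parse_array_key(k)[1] == zt
        ]

    def to_tsv(self, path) -> None:
        write_tsv(self.values, path)


@dataclass(frozen=True)
class DetectionThreshold:
    """Background detection threshold: mean(NC) + multiplier × sd(NC)."""

    value: float
    nc_mean: float
    nc_sd: float
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.value < self.nc_mean:
            raise ValueError("threshold below the negative-control mean")


@dataclass
class QCReport:
    """Replicate-agreement QC: pairwise Pearson r and intrachip CV."""

    replicate_pearson: pd.DataFrame  # condition, array_a, array_b, r
    intrachip_cv: pd.Series          # per-array mean CV over duplicate spots
    min_pearson: float
    mean_cv: float
    passed: bool


# ---------------------------------------------------------------------------
# GC-bin normalization
# ---------------------------------------------------------------------------

def _quantile_map(values: np.ndarray, source_sorted: np.ndarray,
                  ref_sorted: np.ndarray) -> np.ndarray:
    """Map ``values`` through the empirical quantiles of ``source_sorted``
    onto the order statistics of ``ref_sorted`` (linear interpolation)."""
    n, m = len(source_sorted), len(ref_sorted)
    if n == 1:
        q = np.full(len(values), 0.5)
    else:
        q = np.interp(values, source_sorted, np.linspace(0.0, 1.0, n))
    if m == 1:
        return np.full(len(values), ref_sorted[0])
    return np.interp(q * (m - 1), np.arange(m), ref_sorted)


def gc_normalize(matrix: IntensityMatrix, gc: pd.Series,
                 nc_flags: pd.Series | None = None) -> IntensityMatrix:
    """Map every GC bin's log-intensity distribution onto the best-represented
    bin.

    Probes are grouped by integer GC count; the reference bin is the one with
    the most (genomic) probes.  Within each other bin, every value is replaced
    by the reference bin's order statistic at its empirical quantile — a
    monotone, rank-preserving map, so within-bin ordering is untouched.
    Negative controls do not contribute to bin statistics but are pushed
    through their own bin's transform.  Bins with fewer than two genomic
    probes pass through unchanged (with a warning).
    """
    gc = gc.reindex(matrix.values.index)
    if gc.isna().any():
        raise ValueError("every probe needs a GC value")
    if nc_flags is None:
        nc_flags = pd.Series(False, index=matrix.values.index)
    nc_flags = nc_flags.reindex(matrix.values.index).fillna(False).astype(bool)

    logv = matrix.log_values()
    gc_arr = gc.to_numpy(int)
    nc_arr = nc_flags.to_numpy()
    counts = pd.Series(gc_arr[~nc_arr]).value_counts()
    ref_gc = int(counts.idxmax())

    out = logv.to_numpy().copy()
    small: list[int] = []
    for col in range(out.shape[1]):
        vals = logv.to_numpy()[:, col]
        ref_sorted = np.sort(vals[(gc_arr == ref_gc) & ~nc_arr])
        for g in counts.index:
            g = int(g)
            if g == ref_gc:
                continue
            bin_mask = gc_arr == g
            src = np.sort(vals[bin_mask & ~nc_arr])
            if len(src) < 2:
                small.append(g)
                continue
            out[bin_mask, col] = _quantile_map(vals[bin_mask], src, ref_sorted)
        # NC-only bins (no genomic probe shares the GC value) pass through
    if small:
        warnings.warn(
            f"GC bins with <2 probes passed through unchanged: {sorted(set(small))}",
            stacklevel=2,
        )
    values = pd.DataFrame(np.exp(out), index=matrix.values.index,
                          columns=matrix.values.columns)
    return IntensityMatrix(values=values, stage="gc_normalized",
                           duplicate_spots=matrix.duplicate_spots)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Classic cross-array quantile normalization on log intensities.

    Rank each array, replace rank k by the mean across arrays of the k-th
    order statistics; tied values receive the mean of the reference values
    their rank span would have received.  Afterwards every array holds the
    identical multiset of values.  A single-array matrix is returned
    unchanged (bar the stage tag); the operation is idempotent.
    """
    logv = matrix.log_values().to_numpy()
    n, k = logv.shape
    if k == 1:
        values = matrix.values.copy()
        return IntensityMatrix(values=values, stage="quantile_normalized",
                               duplicate_spots=matrix.duplicate_spots)
    ref = np.sort(logv, axis=0).mean(axis=1)  # mean k-th order statistics
    out = np.empty_like(logv)
    for j in range(k):
        col = logv[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # ties: average the reference values over the span of tied ranks
        s = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    values = pd.DataFrame(np.exp(out), index=matrix.values.index,
                          columns=matrix.values.columns)
    return IntensityMatrix(values=values, stage="quantile_normalized",
                           duplicate_spots=matrix.duplicate_spots)


# ---------------------------------------------------------------------------
# detection thresholds
# ---------------------------------------------------------------------------

def detection_threshold(
    array_values: pd.Series, nc_flags: pd.Series, multiplier: float = 2.0,
    log: bool = True,
) -> DetectionThreshold:
    """Per-array detection threshold from the negative controls:
    mean + ``multiplier`` × sample standard deviation (n−1 denominator).

    The pipeline computes thresholds on natural-log intensities (``log``
    default); pass ``log=False`` for values already on the analysis scale.
    Requires at least two controls.
    """
    nc_vals = array_values[
        nc_flags.reindex(array_values.index).fillna(False).astype(bool)
    ]
    if log:
        nc_vals = np.log(nc_vals)
    if len(nc_vals) < 2:
        raise ValueError("need at least 2 negative-control probes")
    mean = float(np.mean(nc_vals))
    sd = float(np.std(nc_vals, ddof=1))
    return DetectionThreshold(value=mean + multiplier * sd, nc_mean=mean, nc_sd=sd)


def condition_thresholds(
    matrix: IntensityMatrix, nc_flags: pd.Series, multiplier: float = 2.0,
    pool: str = "none",
) -> dict[tuple[str, int], DetectionThreshold]:
    """One threshold per (genotype, ZT) condition.

    ``pool`` controls how much NC data feeds each threshold:

    * ``"none"`` — per-array thresholds averaged over the replicates;
    * ``"replicates"`` — the condition's replicate NC values pooled into one
      mean + k·sd computation;
    * ``"global"`` — all arrays' NC values pooled into a single threshold
      shared by every condition.  Since the negative controls estimate a
      background that does not depend on genotype or time, global pooling
      gives the most precise threshold and is what the pipeline driver uses.
    """
    if pool not in ("none", "replicates", "global"):
        raise ValueError("pool must be 'none', 'replicates' or 'global'")
    out: dict[tuple[str, int], DetectionThreshold] = {}
    flags = nc_flags.reindex(matrix.values.index).fillna(False).astype(bool)
    if pool == "global":
        pooled = np.log(matrix.values.loc[flags].to_numpy().ravel())
        mean, sd = float(pooled.mean()), float(pooled.std(ddof=1))
        th = DetectionThreshold(mean + multiplier * sd, mean, sd)
        return {cond: th for cond in matrix.conditions()}
    for (g, zt) in matrix.conditions():
        cols = matrix.condition_columns(g, zt)
        if pool == "replicates":
            pooled = np.log(
                matrix.values.loc[flags, cols].to_numpy().ravel()
            )
            mean, sd = float(pooled.mean()), float(pooled.std(ddof=1))
            out[(g, zt)] = DetectionThreshold(mean + multiplier * sd, mean, sd)
        else:
            ths = [detection_threshold(matrix.values[c], flags, multiplier)
                   for c in cols]
            out[(g, zt)] = DetectionThreshold(
                float(np.mean([t.value for t in ths])),
                float(np.mean([t.nc_mean for t in ths])),
                float(np.mean([t.nc_sd for t in ths])),
            )
    return out


# ---------------------------------------------------------------------------
# QC and replicate pooling
# ---------------------------------------------------------------------------

def qc_replicates(
    matrix: IntensityMatrix,
    duplicate_spots: pd.DataFrame | None = None,
    min_pearson: float = 0.99,
    max_cv: float = 0.20,
    nc_flags: pd.Series | None = None,
) -> QCReport:
    """Replicate-agreement QC.

    Pearson r is computed on log intensities for every replicate pair within
    a condition (negative controls excluded when flags are given — they
    carry no reproducible signal by construction); the intrachip CV is the
    per-probe sd/mean over duplicate spots (intensity scale), averaged per
    array.  Pass requires min r ≥ ``min_pearson`` and mean CV < ``max_cv``.
    """
    if duplicate_spots is None:
        duplicate_spots = matrix.duplicate_spots
    logv = matrix.log_values()
    if nc_flags is not None:
        keep = ~nc_flags.reindex(matrix.values.index).fillna(False).astype(bool)
        logv = logv.loc[keep]
    rows = []
    for (g, zt) in matrix.conditions():
        cols = matrix.condition_columns(g, zt)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = float(stats.pearsonr(logv[cols[i]], logv[cols[j]])[0])
                rows.append(dict(condition=f"{g}_ZT{zt}", array_a=cols[i],
                                 array_b=cols[j], r=r))
    pearson = pd.DataFrame(rows)

    if duplicate_spots is not None and len(duplicate_spots):
        spots = duplicate_spots[["spot1", "spot2"]].to_numpy()
        cv = spots.std(axis=1, ddof=1) / spots.mean(axis=1)
        cv_per_array = (
            pd.Series(cv, index=duplicate_spots["array"]).groupby(level=0).mean()
        )
    else:
        cv_per_array = pd.Series(dtype=float)

    min_r = float(pearson["r"].min()) if len(pearson) else float("nan")
    mean_cv = float(cv_per_array.mean()) if len(cv_per_array) else 0.0
    passed = bool(len(pearson)) and min_r >= min_pearson and mean_cv < max_cv
    return QCReport(replicate_pearson=pearson, intrachip_cv=cv_per_array,
                    min_pearson=min_r, mean_cv=mean_cv, passed=passed)


def average_replicates(matrix: IntensityMatrix, log_scale: bool = True) -> pd.DataFrame:
    """Per-(genotype, ZT) arithmetic mean over replicates.

    The pipeline averages on the log scale (a geometric mean of intensities)
    so the pooled track is directly comparable with the log-scale detection
    thresholds; segment detection consumes this, the windowed rank test does
    not (it sees all replicates).
    """
    data = matrix.log_values() if log_scale else matrix.values
    out = {}
    for (g, zt) in matrix.conditions():
        cols = matrix.condition_columns(g, zt)
        out[f"{g}_ZT{zt}"] = data[cols].mean(axis=1)
    return pd.DataFrame(out, index=matrix.values.index)
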