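# plastotile

Tiling-array analysis of diurnal chloroplast transcription.

Whole-genome tiling arrays probe a circular plastid genome end to end
(35-mer probes every 5 nt), giving annotation-independent transcription
signal for two genotypes — wild type and a cryptochrome-2 overexpressor —
at four zeitgeber times (ZT0 dawn, ZT7 midday, ZT14 dusk, ZT19 midnight)
with three biological replicates each.  `plastotile` implements the full
analysis chain for such an experiment, for researchers who want a tested,
reusable version of the classic tiling-array segmentation workflow:

* **Normalization** — per-array GC-bin quantile mapping (probes grouped by
  integer GC count, each bin mapped onto the best-populated bin), then
  cross-array quantile normalization; detection thresholds from the 54
  negative controls as mean + 2 sd; replicate QC (pairwise Pearson *r*,
  intrachip CV over duplicate spots).
* **Segmentation** — per-probe Hodges–Lehmann smoothing, the pseudomedian
  HL(x) = median{(x_i + x_j)/2 : i ≤ j} over all probes within ±150 nt of
  the focal probe center; *transcribed segments* are maximal runs of probes
  with smoothed level above threshold, joined across gaps ≤ 3×step and kept
  at span ≥ 5×step.
* **Differential expression** — per probe window, a two-tailed unpaired
  Wilcoxon rank-sum test of the pooled (window probes × replicates) samples
  of the two genotypes (exact enumeration for small samples, corrected
  normal approximation otherwise), with the effect measured as the
  difference of Hodges–Lehmann estimates; significant same-direction runs
  become differential regions and genes are called up/down per ZT by
  fractional coverage.
* **5′-end and promoter mapping** — the 5′ boundary of the segment
  overlapping each gene's start codon, condition-to-condition 5′ shifts,
  and motif scans for PEP promoters (TTGACA −35 / TATAAT −10, σ70 geometry)
  and NEP class-Ib promoters (YRTa core + upstream GAA box).
* **Classification and reports** — genic / intronic / intergenic context of
  differential segments, per-ZT up/down matrices, percent-of-ORFs
  summaries.
* **Synthetic data** — a first-class generator
  (`plastotile.synthetic_data`) that builds an annotated toy plastome with
  planted promoters, noncoding loci, injected genotype×time effects and
  5′ truncations, plus probe intensities with the noise structure the
  analysis assumes and a ground-truth table for recovery scoring.

## Worked example

```python
from plastotile import SimConfig
from plastotile.pipeline import (simulate_dataset, run_pipeline,
                                 segmentation_recovery, differential_recovery)

ds = simulate_dataset(SimConfig(), seed=10)   # 40-kb toy plastome, 24 arrays
res = run_pipeline(ds)

print(f"QC: min replicate r = {res.qc.min_pearson:.4f}, "
      f"mean intrachip CV = {res.qc.mean_cv:.3f}, pass = {res.qc.passed}")
print(f"detection threshold (ln scale) = {res.thresholds[('WT', 0)].value:.3f}")
print(sum(len(s) for s in res.segments.values()),
      "transcribed segments across 8 conditions")
rec = segmentation_recovery(ds.truth, res.segments)
print(f"segment recovery: sensitivity = {100*rec.sensitivity.mean():.1f}%, "
      f"background coverage = {100*rec.background_coverage.mean():.1f}%")
de = differential_recovery(ds.truth, ds.annotation, res.calls)
print(f"differential: {de['n_recovered']}/{de['n_expected']} injected effects "
      f"recovered, {de['n_false']} false gene calls")
```

prints

```
QC: min replicate r = 0.9967, mean intrachip CV = 0.095, pass = True
detection threshold (ln scale) = 9.064
269 transcribed segments across 8 conditions
segment recovery: sensitivity = 97.2%, background coverage = 2.8%
differential: 12/12 injected effects recovered, 0 false gene calls
```

That is: replicates agree at the r ≥ 0.99 / CV < 0.20 QC level, the
negative-control threshold lands between background and signal, detected
segments cover 97 % of truly transcribed nucleotides while touching < 3 %
of background, and all twelve injected two-fold genotype×time effects are
recovered with the right direction and no spurious gene calls.

A command-line interface mirrors the stages for file-based work:

```bash
plastotile simulate --out-dir toy --seed 10
plastotile design --genome toy/genome.fa --out probes.tsv
plastotile normalize --in toy/intensities.tsv --probes toy/probes.tsv \
    --genome-length 40000 --out norm.tsv --qc qc.tsv --thresholds thr.tsv
plastotile segment --norm norm.tsv --probes toy/probes.tsv \
    --genome-length 40000 --out segments.bed
plastotile diff --norm norm.tsv --probes toy/probes.tsv --genome toy/genome.fa \
    --annotation toy/annotation.gff3 --out regions.bed --matrix calls.tsv
plastotile tss --segments segments.bed --genome toy/genome.fa \
    --annotation toy/annotation.gff3 --out tss.tsv
plastotile promoters --genome toy/genome.fa --tss tss.tsv --out promoters.tsv
plastotile classify --segments regions.bed --genome toy/genome.fa \
    --annotation toy/annotation.gff3 --out classes.tsv
plastotile report --calls calls.tsv --classes classes.tsv --out report.txt
```

All parameters (bandwidth 150, join ≤ 3×step, span ≥ 5×step, p < 0.05,
threshold multiplier 2, promoter spacings, …) live in a YAML config; see
`plastotile/config.py` for the schema and defaults.

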