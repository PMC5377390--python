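"""Synthetic annotated plastome and probe-intensity generator.

The generator emulates the statistical structure the analysis pipeline
assumes: a circular genome carrying non-overlapping transcription units
(single genes, multi-gene operons, intron-containing genes) separated by
intergenic gaps; planted PEP and NEP class-Ib promoter motifs upstream of
photosynthesis and genetic-system units respectively; noncoding RNA loci in
gaps and inside introns; and 35-mer probe intensities with multiplicative
(log-additive) structure — per-probe GC bias and affinity, heavy-tailed
background heterogeneity, lognormal array noise, per-zeitgeber-time diurnal
modulation, injected genotype×time differential effects and 5′-end
truncations.  A :class:`TruthTable` records everything that was injected so
recovery can be scored.

Model for one genomic probe p on array (genotype g, time t, replicate r)::

    log I = mu(p, g, t) + beta * GC(p) + affinity(p) + noise(p, g, t, r)

where ``mu`` is the log abundance of the transcription unit whose span fully
contains the probe footprint, or the background mean plus a fixed per-probe
background deviation otherwise.  Negative-control probes draw independent
background values on every array.  A probe carries transcript signal only if
its entire footprint lies inside the transcribed span (full-complementarity
hybridization model), so detected segment spans line up with true unit
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    Annotation,
    CircularGenome,
    Gene,
    Intron,
    Operon,
    interval_length,
)
from .probe_design import ProbeSet, reverse_complement

__all__ = [
    "SimConfig",
    "DEEffect",
    "TSSShiftSpec",
    "TruthTable",
    "make_toy_plastome",
    "simulate_intensities",
    "GENOTYPES",
    "ZTS",
    "array_key",
]

GENOTYPES = ("WT", "CRY2OX")
ZTS = (0, 7, 14, 19)

# promoter geometry used when planting motifs (mirrored by the scanner's
# acceptance windows, which are wider)
PEP_MINUS35 = "TTGACA"
PEP_MINUS10 = "TATAAT"
PEP_SPACER = 17        # between -35 end and -10 start
PEP_GAP_TO_TSS = 8     # last base of -10 box sits 8 nt upstream of the TSS
NEP_CORE = "CATA"      # a YRTa realisation (Y=C, R=A, T, a)
NEP_GAA_OFFSET = 23    # GAA start sits 23 nt upstream of the YRTa start


def array_key(genotype: str, zt: int, replicate: int) -> str:
    return f"{genotype}_ZT{zt}_R{replicate}"


@dataclass(frozen=True)
class DEEffect:
    """A genotype×time differential effect injected on a unit or ncRNA locus."""

    target: str
    zts: tuple[int, ...]
    log2fc: float  # CRY2-OX relative to WT; sign gives direction

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class TSSShiftSpec:
    """A 5′ truncation of one unit in one (genotype, ZT) condition."""

    unit: str
    genotype: str
    zt: int
    shift: int  # nt lost from the 5' end (transcript becomes shorter)


@dataclass
class SimConfig:
    """Parameters of the toy plastome and of the intensity model.

    Scale conventions: intensities are strictly positive; all noise terms act
    on the natural-log scale.  The defaults put the transcribed units about
    e^2 ≈ 7× over the mean background, with the negative-control threshold
    (mean + 2 sd) falling halfway between the two levels — the regime in
    which pseudomedian smoothing resolves segment boundaries.
    """

    genome_length: int = 40000
    n_transcription_units: int = 25
    category_proportions: dict = field(
        default_factory=lambda: {"photosynthesis": 0.4, "genetic_system": 0.4,
                                 "other": 0.2}
    )
    n_intergenic_ncrna: int = 8
    n_intronic_ncrna: int = 4
    ncrna_length: int = 200
    intronic_ncrna_length: int = 50

    baseline_log_intensity: float = 9.36
    unit_abundance_sd: float = 0.1
    diurnal_amplitude: dict = field(
        default_factory=lambda: {0: 1.0, 7: 1.08, 14: 1.08, 19: 0.95}
    )
    de_effects: list | None = None          # None -> canonical defaults
    ncrna_de_effects: list | None = None    # None -> canonical defaults
    tss_shift_units: list | None = None     # None -> one 150-nt WT/ZT7 shift

    gc_bias_coeff: float = 0.1              # per GC unit, log scale
    probe_affinity_sd: float = 0.25
    noise_sd: float = 0.12
    nc_background_mean: float = 6.0
    nc_background_sd: float = 0.77          # negative-control spread per array
    background_heterogeneity_sd: float = 0.65  # fixed per-probe, genomic background
    bg_bright_fraction: float = 0.0         # cross-hybridizing bright background
    bg_bright_range: tuple = (0.3, 1.5)     # extra log-intensity of bright probes
    ncrna_abundance_offset: float = 0.0     # ncRNA loci over unit baseline (ln)

    replicates: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("unit_abundance_sd", "probe_affinity_sd", "noise_sd",
                     "nc_background_sd", "background_heterogeneity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if set(self.diurnal_amplitude) - set(ZTS):
            raise ValueError(f"diurnal ZTs must be a subset of {ZTS}")


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    units: pd.DataFrame          # unit, start, end, strand, category, leader, kind
    abundance: pd.DataFrame      # index unit, columns GENOTYPE_ZTx -> ln abundance
    de_effects: list[DEEffect]
    ncrna_de_effects: list[DEEffect]
    tss_shifts: list[TSSShiftSpec]
    promoters: pd.DataFrame      # unit, type, tss, strand + box coordinates
    ncrna: pd.DataFrame          # name, start, end, kind, host
    beta: float
    genome_length: int

    def unit_effective_span(
        self, unit: str, genotype: str, zt: int
    ) -> tuple[int, int]:
        """Transcribed span of a unit in one condition (5′ truncations applied)."""
        row = self.units.set_index("unit").loc[unit]
        start, end, strand = int(row["start"]), int(row["end"]), row["strand"]
        for shift in self.tss_shifts:
            if shift.unit == unit and shift.genotype == genotype and shift.zt == zt:
                if strand == "+":
                    start = (start + shift.shift) % self.genome_length
                else:
                    end = (end - shift.shift) % self.genome_length
        return start, end

    def transcribed_intervals(
        self, genotype: str, zt: int
    ) -> list[tuple[int, int]]:
        """All truly transcribed spans in one condition: units (after any 5′
        truncation) plus intergenic ncRNA loci."""
        spans = [
            self.unit_effective_span(u, genotype, zt)
            for u in self.units["unit"]
        ]
        inter = self.ncrna[self.ncrna["kind"] == "intergenic"]
        spans += [(int(r["start"]), int(r["end"])) for _, r in inter.iterrows()]
        return spans

    def true_log_abundance(self, target: str, genotype: str, zt: int) -> float:
        return float(self.abundance.loc[target, array_key(genotype, zt, 0)[:-3]])


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _default_de_effects(unit_roles: dict[str, str]) -> list[DEEffect]:
    simple = [u for u, role in unit_roles.items() if role == "simple"]
    ups, downs = simple[:3], simple[3:6]
    return [DEEffect(u, (7, 14), +1.0) for u in ups] + [
        DEEffect(u, (7, 14), -1.0) for u in downs
    ]


def _default_ncrna_de_effects(names: list[str], intronic: list[str]) -> list[DEEffect]:
    inter = [n for n in names if n not in intronic]
    effects: list[DEEffect] = []
    if len(inter) >= 4:
        effects += [
            DEEffect(inter[0], (7, 14), +1.0),
            DEEffect(inter[1], (7, 14), +1.0),
            DEEffect(inter[2], (7, 14), -1.0),
            DEEffect(inter[3], (7, 14), -1.0),
        ]
    if len(inter) >= 6:
        effects += [DEEffect(inter[4], (19,), +1.0),
                    DEEffect(inter[5], (0,), -1.0)]
    if len(intronic) >= 2:
        effects += [DEEffect(intronic[0], (0, 19), +1.0),
                    DEEffect(intronic[1], (0, 19), -1.0)]
    return effects


def _unit_blueprints(config: SimConfig) -> list[dict]:
    """Fixed blueprint mix: intron hosts, operons, one long-leader unit for
    5′-shift injection, and simple single-gene units."""
    n = config.n_transcription_units
    bp: list[dict] = []
    n_hosts = min(config.n_intronic_ncrna, n)
    for _ in range(n_hosts):
        bp.append(dict(kind="intron_host", length=800, leader=40, n_genes=1))
    n_operons = min(5, max(0, n - n_hosts - 1))
    for k in range(n_operons):
        bp.append(dict(kind="operon", length=420, leader=40, n_genes=2 + k % 2))
    if n > n_hosts + n_operons:
        bp.append(dict(kind="tss_shift", length=520, leader=200, n_genes=1))
    while len(bp) < n:
        bp.append(dict(kind="simple", length=500, leader=40, n_genes=1))
    return bp[:n]


def make_toy_plastome(
    config: SimConfig, seed: int
) -> tuple[CircularGenome, Annotation, TruthTable]:
    """Generate a toy annotated circular plastome plus its ground truth.

    Units are placed in random order with jittered intergenic gaps; each
    photosynthesis unit gets an exact PEP promoter (TTGACA/TATAAT) planted
    upstream of its transcription start, each genetic-system unit an exact NEP
    class-Ib promoter (GAA box + YRTa core).  Intergenic ncRNA loci are
    centred in gaps, intronic ones inside introns.  Same seed, same bytes.
    """
    rng = np.random.default_rng(seed)
    L = config.genome_length
    blueprints = _unit_blueprints(config)
    n = len(blueprints)

    total_units = sum(b["length"] for b in blueprints)
    min_gap = 120  # room for promoter + margins
    if total_units + n * min_gap > L:
        raise ValueError(
            f"cannot place {n} units totalling {total_units} nt on a "
            f"{L}-nt genome without overlap; increase genome_length"
        )

    order = rng.permutation(n)
    blueprints = [blueprints[i] for i in order]

    # categories by proportion; the 5'-shift unit is forced photosynthesis so
    # the injected truncation has a PEP promoter context
    cats: list[str] = []
    for cat, frac in config.category_proportions.items():
        cats += [cat] * int(round(frac * n))
    while len(cats) < n:
        cats.append("other")
    cats = list(rng.permutation(cats[:n]))
    for i, b in enumerate(blueprints):
        if b["kind"] == "tss_shift":
            j = cats.index("photosynthesis") if "photosynthesis" in cats else i
            cats[i], cats[j] = cats[j], cats[i]

    # gap sizes: jittered, summing to the leftover space
    spare = L - total_units
    if n:
        raw = rng.uniform(0.6, 1.4, size=n)
        gaps = np.floor(raw / raw.sum() * spare).astype(int)
        gaps[-1] += spare - gaps.sum()
    else:
        gaps = np.array([], dtype=int)

    seq = rng.choice(list("ACGT"), size=L, p=[0.3, 0.2, 0.2, 0.3])  # AT-rich, like real plastomes
    genes: list[Gene] = []
    introns: list[Intron] = []
    operons: list[Operon] = []
    unit_rows, promoter_rows, ncrna_rows = [], [], []
    intronic_sites: list[tuple[str, int, int]] = []  # (gene, start, end) of introns
    gap_midpoints: list[int] = []

    pos = int(gaps[0] // 2) if n else 0
    for i, (b, cat) in enumerate(zip(blueprints, cats)):
        strand = "-" if i % 4 == 3 else "+"
        start, end = pos, pos + b["length"]
        name = f"TU{i + 1:02d}"
        unit_rows.append(
            dict(unit=name, start=start, end=end, strand=strand,
                 category=cat, leader=b["leader"], kind=b["kind"])
        )
        # genes inside the unit (oriented): leader, then genes with 20-nt
        # intercistronic spacers
        body = b["length"] - b["leader"]
        ng = b["n_genes"]
        spacer = 20 if ng > 1 else 0
        glen = (body - spacer * (ng - 1)) // ng
        gene_names = []
        for k in range(ng):
            off = b["leader"] + k * (glen + spacer)
            if strand == "+":
                gs, ge = start + off, start + off + glen
            else:
                ge = end - off
                gs = ge - glen
            gname = f"{name}g{k + 1}" if ng > 1 else name + "g1"
            genes.append(Gene(gname, gs % L, ge if ge <= L else ge % L,
                              strand, cat))
            gene_names.append(gname)
        if ng > 1:
            operons.append(Operon(f"op_{name}", tuple(gene_names),
                                  start if strand == "+" else end - 1))
        if b["kind"] == "intron_host":
            # one 100-nt intron in the middle of the single gene
            g = genes[-1]
            ioff = 330
            if strand == "+":
                istart = g.start + ioff
            else:
                istart = g.end - ioff - 100
            introns.append(Intron(g.name, istart % L, (istart + 100) % L or L))
            intronic_sites.append((g.name, istart, istart + 100))
        # planted promoter upstream of the unit TSS
        tss = start if strand == "+" else end  # 5' boundary in gene orientation
        if cat == "photosynthesis":
            promoter_rows.append(
                _plant_pep(seq, tss, strand, L)
                | dict(unit=name, type="PEP", strand=strand)
            )
        elif cat == "genetic_system":
            promoter_rows.append(
                _plant_nep_ib(seq, tss, strand, L)
                | dict(unit=name, type="NEP_Ib", strand=strand)
            )
        # start codons for realism
        for g in genes[-ng:]:
            _write_oriented(seq, "ATG", g.start if g.strand == "+" else g.end - 3,
                            g.strand, L)
        pos = end + int(gaps[i] if i < n - 1 else gaps[-1])
        gap_midpoints.append((end + 60 + pos - 60) // 2)

    # intergenic ncRNA loci: centred in the widest gaps, clear of promoters
    gap_order = np.argsort(-gaps[: len(gap_midpoints)])
    half = config.ncrna_length // 2
    count = 0
    for gi in gap_order:
        if count >= config.n_intergenic_ncrna:
            break
        mid = gap_midpoints[gi] % L
        ncrna_rows.append(
            dict(name=f"ncR{count + 1:02d}", start=(mid - half) % L,
                 end=(mid - half + config.ncrna_length) % L or L,
                 kind="intergenic", host="")
        )
        count += 1
    # intronic ncRNA loci: centred inside the planted introns
    for k, (gname, istart, iend) in enumerate(
        intronic_sites[: config.n_intronic_ncrna]
    ):
        mid = (istart + iend) // 2
        s = (mid - config.intronic_ncrna_length // 2) % L
        ncrna_rows.append(
            dict(name=f"ncI{k + 1:02d}", start=s,
                 end=(s + config.intronic_ncrna_length) % L or L,
                 kind="intronic", host=gname)
        )

    genome = CircularGenome("toy_plastome", "".join(seq))
    annotation = Annotation(genes=genes, introns=introns, operons=operons,
                            genome_length=L)

    units_df = pd.DataFrame(unit_rows) if unit_rows else pd.DataFrame(
        columns=["unit", "start", "end", "strand", "category", "leader", "kind"]
    )
    ncrna_df = pd.DataFrame(ncrna_rows) if ncrna_rows else pd.DataFrame(
        columns=["name", "start", "end", "kind", "host"]
    )
    promoters_df = pd.DataFrame(promoter_rows) if promoter_rows else pd.DataFrame(
        columns=["unit", "type", "tss", "strand"]
    )

    roles = {r["unit"]: r["kind"] for r in unit_rows}
    de = (config.de_effects if config.de_effects is not None
          else _default_de_effects(roles))
    nc_names = list(ncrna_df["name"])
    intronic_names = list(ncrna_df.loc[ncrna_df["kind"] == "intronic", "name"])
    nde = (config.ncrna_de_effects if config.ncrna_de_effects is not None
           else _default_ncrna_de_effects(nc_names, intronic_names))
    if config.tss_shift_units is not None:
        shifts = list(config.tss_shift_units)
    else:
        tss_units = [r["unit"] for r in unit_rows if r["kind"] == "tss_shift"]
        shifts = [TSSShiftSpec(tss_units[0], "WT", 7, 150)] if tss_units else []

    known = set(units_df["unit"]) | set(nc_names)
    for eff in list(de) + list(nde):
        if eff.target not in known:
            raise ValueError(f"injected effect references unknown unit {eff.target!r}")
    for sh in shifts:
        row = units_df.set_index("unit").loc[sh.unit]
        if sh.shift >= interval_length(int(row["start"]), int(row["end"]), L):
            raise ValueError(f"5' shift {sh.shift} exceeds unit {sh.unit} length")

    abundance = _abundance_table(config, units_df, ncrna_df, de, nde, rng)
    truth = TruthTable(
        units=units_df, abundance=abundance, de_effects=list(de),
        ncrna_de_effects=list(nde), tss_shifts=shifts,
        promoters=promoters_df, ncrna=ncrna_df,
        beta=config.gc_bias_coeff, genome_length=L,
    )
    return genome, annotation, truth


def _write_oriented(seq: np.ndarray, motif: str, start: int, strand: str,
                    L: int) -> None:
    s = motif if strand == "+" else reverse_complement(motif)
    for k, ch in enumerate(s):
        seq[(start + k) % L] = ch


def _plant_pep(seq: np.ndarray, tss: int, strand: str, L: int) -> dict:
    """Plant TTGACA +17nt+ TATAAT, the −10 box ending 8 nt upstream of the TSS.

    Returns oriented genome coordinates of the planted boxes (first base of
    each box in transcript orientation).
    """
    def up(d: int) -> int:  # genome coord of the base d nt upstream of the TSS
        return (tss - d) % L if strand == "+" else (tss + d - 1) % L

    m10_first_up = PEP_GAP_TO_TSS + len(PEP_MINUS10) - 1  # offset of box start
    m35_first_up = m10_first_up + PEP_SPACER + len(PEP_MINUS35)
    if strand == "+":
        _write_oriented(seq, PEP_MINUS10, (tss - m10_first_up) % L, "+", L)
        _write_oriented(seq, PEP_MINUS35, (tss - m35_first_up) % L, "+", L)
    else:
        _write_oriented(seq, PEP_MINUS10, (tss + PEP_GAP_TO_TSS - 1) % L, "-", L)
        _write_oriented(seq, PEP_MINUS35,
                        (tss + m35_first_up - len(PEP_MINUS35)) % L, "-", L)
    return dict(tss=tss, minus10_start=up(m10_first_up), minus35_start=up(m35_first_up))


def _plant_nep_ib(seq: np.ndarray, tss: int, strand: str, L: int) -> dict:
    """Plant GAA + 20 random nt + CATA with the final A at TSS−1."""
    core_first_up = len(NEP_CORE)  # YRTa spans offsets 4..1 upstream
    gaa_first_up = core_first_up + NEP_GAA_OFFSET
    if strand == "+":
        _write_oriented(seq, NEP_CORE, (tss - core_first_up) % L, "+", L)
        _write_oriented(seq, "GAA", (tss - gaa_first_up) % L, "+", L)
    else:
        _write_oriented(seq, NEP_CORE, tss % L, "-", L)
        _write_oriented(seq, "GAA", (tss + gaa_first_up - 3) % L, "-", L)
    up = (lambda d: (tss - d) % L) if strand == "+" else (lambda d: (tss + d - 1) % L)
    return dict(tss=tss, core_start=up(core_first_up), gaa_start=up(gaa_first_up))


def _abundance_table(
    config: SimConfig,
    units_df: pd.DataFrame,
    ncrna_df: pd.DataFrame,
    de: Sequence[DEEffect],
    nde: Sequence[DEEffect],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """ln abundance per (unit or ncRNA locus) × (genotype, ZT)."""
    ln2 = np.log(2.0)
    de_map: dict[tuple[str, int], float] = {}
    for eff in list(de) + list(nde):
        for zt in eff.zts:
            de_map[(eff.target, zt)] = eff.log2fc * ln2

    rows = {}
    base_by_target = {}
    for _, r in units_df.iterrows():
        base_by_target[r["unit"]] = (
            config.baseline_log_intensity
            + rng.normal(0.0, config.unit_abundance_sd)
        )
    host_of = {}
    for _, r in ncrna_df.iterrows():
        if r["kind"] == "intergenic":
            base_by_target[r["name"]] = (
                config.baseline_log_intensity + config.ncrna_abundance_offset
                + rng.normal(0.0, config.unit_abundance_sd)
            )
        else:
            # intronic locus rides on its host unit's transcript
            host_unit = r["host"][:4]  # gene names are "<unit>g<k>"
            host_of[r["name"]] = host_unit

    for target, base in list(base_by_target.items()):
        for g in GENOTYPES:
            for zt in ZTS:
                val = base + np.log(config.diurnal_amplitude.get(zt, 1.0))
                if g == "CRY2OX" and (target, zt) in de_map:
                    val += de_map[(target, zt)]
                rows.setdefault(target, {})[f"{g}_ZT{zt}"] = val
    for name, host in host_of.items():
        for g in GENOTYPES:
            for zt in ZTS:
                val = rows[host][f"{g}_ZT{zt}"]
                if g == "CRY2OX" and (name, zt) in de_map:
                    val += de_map[(name, zt)]
                rows.setdefault(name, {})[f"{g}_ZT{zt}"] = val
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# intensity simulation
# ---------------------------------------------------------------------------

def _footprint_inside(
    starts: np.ndarray, probe_length: int, span: tuple[int, int], L: int
) -> np.ndarray:
    """Mask of probes whose full footprint lies inside a circular span."""
    s, e = span
    span_len = interval_length(s, e, L)
    off = (starts - s) % L
    return off + probe_length <= span_len


def simulate_intensities(
    probe_set: ProbeSet,
    annotation: Annotation,
    truth: TruthTable,
    config: SimConfig,
    seed: int,
):
    """Simulate the full 2-genotype × 4-ZT × n-replicate intensity matrix.

    Returns an :class:`~plastotile.normalization.IntensityMatrix` whose
    ``duplicate_spots`` attribute holds the second spot of every
    replicate-tagged probe (for intrachip CV QC).  Noise streams are split
    deterministically from the master seed, one per array, so any subset of
    arrays is reproducible.
    """
    from .normalization import IntensityMatrix

    if probe_set.genome_length != truth.genome_length:
        raise ValueError("probe set and truth table were built on different genomes")
    L = truth.genome_length
    table = probe_set.table
    n_probes = len(table)
    genomic_mask = ~table["is_nc"].to_numpy()
    starts = np.where(genomic_mask, table["start"].fillna(0).to_numpy(np.int64), 0)
    gc = table["gc"].to_numpy(float)
    plen = probe_set.probe_length

    ss = np.random.SeedSequence(seed)
    n_arrays = 2 * len(ZTS) * config.replicates
    children = ss.spawn(n_arrays + 2)
    rng_fixed = np.random.default_rng(children[0])

    affinity = rng_fixed.normal(0.0, config.probe_affinity_sd, size=n_probes)
    bg_dev = rng_fixed.normal(0.0, config.background_heterogeneity_sd,
                              size=n_probes)
    # a minority of background probes cross-hybridize and sit anywhere up to
    # transcript-level brightness; they populate the intensity range between
    # the background bulk and true signal
    bright = rng_fixed.random(n_probes) < config.bg_bright_fraction
    bg_dev = bg_dev + bright * rng_fixed.uniform(
        config.bg_bright_range[0], config.bg_bright_range[1], size=n_probes
    )

    # per-condition per-probe base mean (before GC/affinity/noise)
    cond_mu: dict[str, np.ndarray] = {}
    for g in GENOTYPES:
        for zt in ZTS:
            mu = np.full(n_probes, config.nc_background_mean) + bg_dev
            for _, r in truth.units.iterrows():
                span = truth.unit_effective_span(r["unit"], g, zt)
                mask = genomic_mask & _footprint_inside(starts, plen, span, L)
                mu[mask] = truth.abundance.loc[r["unit"], f"{g}_ZT{zt}"]
            for _, r in truth.ncrna.iterrows():
                span = (int(r["start"]), int(r["end"]))
                mask = genomic_mask & _footprint_inside(starts, plen, span, L)
                mu[mask] = truth.abundance.loc[r["name"], f"{g}_ZT{zt}"]
            cond_mu[f"{g}_ZT{zt}"] = mu

    shared = affinity + config.gc_bias_coeff * gc
    nc_mask = ~genomic_mask

    columns: dict[str, np.ndarray] = {}
    dup_mask = table["replicate_group"].notna().to_numpy()
    dup_rows = []
    k = 1
    for g in GENOTYPES:
        for zt in ZTS:
            for rep in range(1, config.replicates + 1):
                rng = np.random.default_rng(children[k])
                k += 1
                mu = cond_mu[f"{g}_ZT{zt}"] + shared
                # negative controls: fresh background draw on every array
                nc_draw = rng.normal(config.nc_background_mean,
                                     config.nc_background_sd,
                                     size=int(nc_mask.sum()))
                mu = mu.copy()
                mu[nc_mask] = (nc_draw
                               + config.gc_bias_coeff * gc[nc_mask]
                               + affinity[nc_mask])
                noise = rng.normal(0.0, config.noise_sd, size=n_probes)
                spot1 = np.exp(mu + noise)
                key = array_key(g, zt, rep)
                noise2 = rng.normal(0.0, config.noise_sd, size=int(dup_mask.sum()))
                spot2 = np.exp(mu[dup_mask] + noise2)
                values = spot1.copy()
                values[dup_mask] = 0.5 * (spot1[dup_mask] + spot2)
                columns[key] = values
                dup_rows.append(
                    pd.DataFrame(
                        {
                            "probe_id": table.loc[dup_mask, "id"].to_numpy(),
                            "array": key,
                            "spot1": spot1[dup_mask],
                            "spot2": spot2,
                        }
                    )
                )

    values = pd.DataFrame(columns, index=pd.Index(table["id"], name="probe_id"))
    matrix = IntensityMatrix(values=values, stage="raw")
    matrix.duplicate_spots = pd.concat(dup_rows, ignore_index=True)
    return matrix
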