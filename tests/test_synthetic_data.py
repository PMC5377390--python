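"""Generator correctness: determinism, planted structure, noise law."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastotile.io_formats import interval_contains, write_fasta, write_gff3
from plastotile.probe_design import reverse_complement, tile_probes
from plastotile.synthetic_data import (
    DEEffect,
    SimConfig,
    make_toy_plastome,
    simulate_intensities,
)


SMALL = dict(genome_length=12000, n_transcription_units=8,
             n_intergenic_ncrna=3, n_intronic_ncrna=2)


def test_same_seed_byte_identical(tmp_path):
    cfg = SimConfig(**SMALL)
    files = []
    for run in ("a", "b"):
        genome, ann, _ = make_toy_plastome(cfg, seed=11)
        fa = tmp_path / f"{run}.fa"
        gff = tmp_path / f"{run}.gff3"
        write_fasta(genome, fa)
        write_gff3(ann, genome.id, gff)
        files.append((fa.read_bytes(), gff.read_bytes()))
    assert files[0] == files[1]


def test_no_units_empty_truth():
    cfg = SimConfig(genome_length=5000, n_transcription_units=0,
                    n_intergenic_ncrna=0, n_intronic_ncrna=0,
                    de_effects=[], ncrna_de_effects=[], tss_shift_units=[])
    genome, ann, truth = make_toy_plastome(cfg, seed=1)
    assert genome.length == 5000
    assert not ann.genes and truth.units.empty and truth.ncrna.empty


def test_units_do_not_overlap():
    _, _, truth = make_toy_plastome(SimConfig(**SMALL), seed=3)
    spans = sorted(zip(truth.units["start"], truth.units["end"]))
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


def test_cannot_place_units_raises():
    with pytest.raises(ValueError, match="genome_length"):
        make_toy_plastome(SimConfig(genome_length=3000), seed=1)


def test_effects_must_reference_known_units():
    cfg = SimConfig(**SMALL, de_effects=[DEEffect("NOPE", (7,), 1.0)])
    with pytest.raises(ValueError, match="unknown unit"):
        make_toy_plastome(cfg, seed=1)


def test_planted_pep_promoters_exact(default_dataset):
    """Every photosynthesis unit carries exact TTGACA/TATAAT boxes upstream
    of its transcription start, in transcript orientation."""
    genome = default_dataset.genome
    truth = default_dataset.truth
    pep = truth.promoters[truth.promoters["type"] == "PEP"]
    assert len(pep) > 0
    for _, p in pep.iterrows():
        tss, strand = int(p["tss"]), p["strand"]
        if strand == "+":
            upstream = genome.fetch(tss - 40, tss)
        else:
            upstream = reverse_complement(genome.fetch(tss, tss + 40))
        assert "TTGACA" in upstream and "TATAAT" in upstream
        # geometry: -10 box ends 8 nt upstream, spacer 17
        i10 = upstream.rindex("TATAAT")
        assert len(upstream) - (i10 + 6) == 7  # 7 random nt then the TSS
        i35 = upstream.rindex("TTGACA")
        assert i10 - (i35 + 6) == 17


def test_planted_nep_promoters_exact(default_dataset):
    genome = default_dataset.genome
    truth = default_dataset.truth
    nep = truth.promoters[truth.promoters["type"] == "NEP_Ib"]
    assert len(nep) > 0
    for _, p in nep.iterrows():
        tss, strand = int(p["tss"]), p["strand"]
        if strand == "+":
            core = genome.fetch(tss - 4, tss)
        else:
            core = reverse_complement(genome.fetch(tss, tss + 4))
        assert core[0] in "CT" and core[1] in "AG" and core[2:] == "TA"


def test_intronic_ncrna_inside_introns(default_dataset):
    truth = default_dataset.truth
    ann = default_dataset.annotation
    L = truth.genome_length
    for _, r in truth.ncrna[truth.ncrna["kind"] == "intronic"].iterrows():
        intr = [i for i in ann.introns if i.parent == r["host"]][0]
        assert interval_contains(intr.start, intr.end, int(r["start"]), L)
        assert interval_contains(intr.start, intr.end, int(r["end"]) - 1, L)


def test_same_seed_identical_matrix():
    cfg = SimConfig(**SMALL)
    genome, ann, truth = make_toy_plastome(cfg, seed=5)
    probes = tile_probes(genome)
    m1 = simulate_intensities(probes, ann, truth, cfg, seed=9)
    m2 = simulate_intensities(probes, ann, truth, cfg, seed=9)
    pd.testing.assert_frame_equal(m1.values, m2.values)


def test_genome_mismatch_errors():
    cfg = SimConfig(**SMALL)
    genome, ann, truth = make_toy_plastome(cfg, seed=5)
    other, _, _ = make_toy_plastome(
        SimConfig(**{**SMALL, "genome_length": 14000}), seed=5)
    with pytest.raises(ValueError, match="different genomes"):
        simulate_intensities(tile_probes(other), ann, truth, cfg, seed=1)


def test_degenerate_noise_gives_identical_replicates():
    """With all noise terms at zero and flat modulation, a unit's probes are
    identical across replicate arrays."""
    cfg = SimConfig(**SMALL, probe_affinity_sd=0.0, noise_sd=0.0,
                    unit_abundance_sd=0.0,
                    background_heterogeneity_sd=0.0,
                    diurnal_amplitude={0: 1, 7: 1, 14: 1, 19: 1},
                    de_effects=[], ncrna_de_effects=[], tss_shift_units=[])
    genome, ann, truth = make_toy_plastome(cfg, seed=2)
    probes = tile_probes(genome)
    m = simulate_intensities(probes, ann, truth, cfg, seed=3)
    genomic = ~probes.table["is_nc"].to_numpy()
    vals = m.values.to_numpy()[genomic]
    assert np.allclose(vals, vals[:, :1])


def test_injected_fold_change_visible_in_raw_signal(default_dataset):
    """A +1 log2 effect at ZT14 doubles the CRY2-OX/WT probe-mean ratio
    inside the unit."""
    truth = default_dataset.truth
    eff = [e for e in truth.de_effects if e.log2fc > 0][0]
    row = truth.units.set_index("unit").loc[eff.target]
    t = default_dataset.probes.table
    starts = t["start"].fillna(-1).to_numpy(int)
    inside = (starts >= row["start"]) & (starts + 35 <= row["end"])
    lv = np.log(default_dataset.raw.values)
    a = lv[[f"CRY2OX_ZT14_R{r}" for r in (1, 2, 3)]].to_numpy()[inside].mean()
    b = lv[[f"WT_ZT14_R{r}" for r in (1, 2, 3)]].to_numpy()[inside].mean()
    assert np.isclose(a - b, np.log(2), atol=0.1)


def test_nc_distribution_condition_invariant(default_dataset):
    """Negative-control intensities follow one law across genotypes and
    times (two-sample KS on pooled replicate values)."""
    m = default_dataset.raw
    nc = default_dataset.probes.table["is_nc"].to_numpy()
    pools = {}
    for (g, zt) in m.conditions():
        cols = m.condition_columns(g, zt)
        pools[(g, zt)] = np.log(m.values.loc[nc, cols]).to_numpy().ravel()
    ref = pools[("WT", 0)]
    for key, vals in pools.items():
        if key == ("WT", 0):
            continue
        assert stats.ks_2samp(ref, vals).pvalue > 0.01


def test_gc_bias_visible_before_normalization():
    """With β = 0.1 the probe GC count correlates with raw log intensity.

    Asserted on background probes of a reduced-heterogeneity configuration:
    under the default background spread the GC term is a small variance
    share and the rank correlation is diluted below any useful level.
    """
    cfg = SimConfig(**SMALL, background_heterogeneity_sd=0.3,
                    de_effects=[], ncrna_de_effects=[], tss_shift_units=[])
    genome, ann, truth = make_toy_plastome(cfg, seed=4)
    probes = tile_probes(genome)
    m = simulate_intensities(probes, ann, truth, cfg, seed=6)
    t = probes.table
    starts = t["start"].fillna(-1).to_numpy(int)
    in_unit = np.zeros(len(t), bool)
    for _, u in truth.units.iterrows():
        in_unit |= (starts >= u["start"]) & (starts + 35 <= u["end"])
    for _, r in truth.ncrna.iterrows():
        in_unit |= (starts >= r["start"]) & (starts + 35 <= r["end"])
    bg = ~in_unit & ~t["is_nc"].to_numpy()
    col = m.values.columns[0]
    rho = stats.spearmanr(t["gc"].to_numpy()[bg],
                          np.log(m.values[col]).to_numpy()[bg])[0]
    assert rho > 0.3


def test_replicate_pearson_matches_qc_regime(default_result):
    """The generator operates in the published QC regime: replicate r ≥ 0.99
    and intrachip CV < 0.20."""
    qc = default_result.qc
    assert qc.min_pearson >= 0.99
    assert qc.mean_cv < 0.20
    assert qc.passed
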