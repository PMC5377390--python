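"""Tiling-probe design over a circular genome.

Probes are ``probe_length``-mers (default 35) laid down every ``step``
nucleotides (default 5) as measured between the central positions of adjacent
probes, so neighbours overlap by ``probe_length − step`` nt and the whole
circle is covered end to end.  A probe's position for all window arithmetic
downstream is its **center**.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CircularGenome, write_tsv, read_tsv

__all__ = [
    "ProbeSet",
    "tile_probes",
    "compute_gc",
    "add_negative_controls",
    "mark_replicated",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def compute_gc(sequence: str) -> int:
    """Count of G plus C in a probe sequence."""
    return sequence.count("G") + sequence.count("C")


@dataclass
class ProbeSet:
    """Ordered collection of tiled probes plus the negative controls.

    ``table`` columns: ``id``, ``start`` (0-based, nullable for negative
    controls), ``length``, ``gc``, ``is_nc``, ``replicate_group``, ``sequence``.
    Genomic probes come first, sorted by start.
    """

    table: pd.DataFrame
    step: int = 5
    probe_length: int = 35
    genome_length: int = 0
    genome_id: str = "genome"

    @property
    def genomic(self) -> pd.DataFrame:
        return self.table[~self.table["is_nc"]]

    @property
    def negative_controls(self) -> pd.DataFrame:
        return self.table[self.table["is_nc"]]

    def centers(self) -> np.ndarray:
        """Center positions of the genomic probes (mod genome length)."""
        starts = self.genomic["start"].to_numpy(dtype=np.int64)
        return (starts + (self.probe_length - 1) // 2) % self.genome_length

    def to_tsv(self, path) -> None:
        write_tsv(self.table, path, index=False)

    @classmethod
    def from_tsv(cls, path, step: int, probe_length: int, genome_length: int,
                 genome_id: str = "genome") -> "ProbeSet":
        t = read_tsv(path, index_col=None)
        t["start"] = t["start"].astype("Int64")
        t["replicate_group"] = t["replicate_group"].astype("string")
        return cls(t, step=step, probe_length=probe_length,
                   genome_length=genome_length, genome_id=genome_id)


def tile_probes(
    genome: CircularGenome, probe_length: int = 35, step: int = 5,
    both_strands: bool = False,
) -> ProbeSet:
    """Tile ``ceil(L/step)`` probes over the circular genome.

    The last probes wrap through the origin so every nucleotide is covered
    whenever ``step ≤ probe_length``.  The analysis pipeline works on one
    reference strand (random-primed targets hybridize both); set
    ``both_strands`` to add reverse-complement probes at the same starts.
    """
    if step < 1:
        raise ValueError("step must be ≥ 1")
    if probe_length > genome.length:
        raise ValueError("probe_length exceeds genome length")
    if step > probe_length:
        warnings.warn("step > probe_length: tiling leaves gaps", stacklevel=2)
    L = genome.length
    n = -(-L // step)  # ceil
    starts = np.arange(n, dtype=np.int64) * step % L
    doubled = genome.sequence + genome.sequence
    seqs = [doubled[s : s + probe_length] for s in starts]
    all_starts = list(starts)
    all_seqs = list(seqs)
    ids = [f"p{int(s):07d}" for s in starts]
    strands = ["+"] * n
    if both_strands:
        all_starts += list(starts)
        all_seqs += [reverse_complement(s) for s in seqs]
        ids += [f"m{int(s):07d}" for s in starts]
        strands += ["-"] * n
    table = pd.DataFrame(
        {
            "id": ids,
            "start": pd.array(all_starts, dtype="Int64"),
            "length": probe_length,
            "gc": [compute_gc(s) for s in all_seqs],
            "is_nc": False,
            "strand": strands,
            "replicate_group": pd.array([None] * len(ids), dtype="string"),
            "sequence": all_seqs,
        }
    )
    return ProbeSet(table, step=step, probe_length=probe_length,
                    genome_length=L, genome_id=genome.id)


def add_negative_controls(
    probe_set: ProbeSet,
    n_nc: int,
    genome: CircularGenome,
    seed: int,
    max_tries: int = 1000,
    gc_range: tuple[int, int] | str | None = "modal",
) -> ProbeSet:
    """Append ``n_nc`` random probes with no exact match in the genome.

    Candidate sequences are rejection-sampled against both strands of the
    (circularised) genome; by default (``gc_range="modal"``) they are also
    constrained to the modal GC count of the genomic probes, mirroring the
    practice of designing controls with the array's typical base composition
    (it also keeps the controls in the best-populated GC bin, where
    downstream GC normalization is best determined).  Negative controls
    carry no genome coordinate.
    """
    if n_nc < 0:
        raise ValueError("n_nc must be ≥ 0")
    if n_nc == 0:
        return probe_set
    if isinstance(gc_range, str):
        if gc_range != "modal":
            raise ValueError("gc_range must be a pair, None, or 'modal'")
        mode = int(probe_set.genomic["gc"].mode().iloc[0])
        gc_range = (mode, mode)
    rng = np.random.default_rng(seed)
    doubled = genome.sequence + genome.sequence[: probe_set.probe_length]
    doubled_rc = reverse_complement(doubled)
    rows = []
    for k in range(n_nc):
        for _ in range(max_tries):
            seq = "".join(rng.choice(list("ACGT"), size=probe_set.probe_length))
            if gc_range is not None and not (
                gc_range[0] <= compute_gc(seq) <= gc_range[1]
            ):
                continue
            if seq not in doubled and seq not in doubled_rc:
                break
        else:
            raise RuntimeError("could not sample a non-matching control sequence")
        rows.append(
            {
                "id": f"NC{k + 1:03d}",
                "start": pd.NA,
                "length": probe_set.probe_length,
                "gc": compute_gc(seq),
                "is_nc": True,
                "strand": ".",
                "replicate_group": pd.NA,
                "sequence": seq,
            }
        )
    nc = pd.DataFrame(rows)
    nc["start"] = nc["start"].astype("Int64")
    nc["replicate_group"] = nc["replicate_group"].astype("string")
    table = pd.concat([probe_set.table, nc], ignore_index=True)
    return ProbeSet(table, step=probe_set.step, probe_length=probe_set.probe_length,
                    genome_length=probe_set.genome_length,
                    genome_id=probe_set.genome_id)


def mark_replicated(probe_set: ProbeSet, fraction: float, seed: int) -> ProbeSet:
    """Tag ``floor(fraction × n)`` genomic probes for on-chip duplication.

    The simulator emits two spots for tagged probes; they are collapsed to one
    intensity by arithmetic mean at load time and used for intrachip CV QC.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    table = probe_set.table.copy()
    genomic_idx = table.index[~table["is_nc"]]
    n_tag = int(fraction * len(genomic_idx))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(genomic_idx.to_numpy(), size=n_tag, replace=False)
    table.loc[:, "replicate_group"] = pd.array([None] * len(table), dtype="string")
    table.loc[chosen, "replicate_group"] = "dup"
    return ProbeSet(table, step=probe_set.step, probe_length=probe_set.probe_length,
                    genome_length=probe_set.genome_length,
                    genome_id=probe_set.genome_id)
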