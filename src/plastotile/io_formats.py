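"""Readers/writers for the external formats the pipeline touches, and the
coordinate conventions shared by every other module.

Coordinate contract
-------------------
All in-memory coordinates are **0-based half-open** intervals on a circular
genome of length ``L``.  An interval with ``start > end`` wraps through the
origin (it covers ``[start, L) ∪ [0, end)``).  Conversion to the external
conventions happens only in this module:

* GFF3 — 1-based, inclusive;
* BED — 0-based, half-open (wrapped intervals are split into two records
  sharing a name);
* WIG — 1-based ``fixedStep``.

The pipeline analyses a single reference strand (the amplification protocol
emulated here is random-primed and effectively unstranded); annotation strand
is used only to orient "upstream of ATG" arithmetic in the TSS/promoter stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

__all__ = [
    "CircularGenome",
    "Gene",
    "Intron",
    "Operon",
    "Annotation",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_bed",
    "read_bed",
    "write_wig",
    "write_tsv",
    "read_tsv",
    "interval_length",
    "interval_contains",
    "intervals_overlap_length",
    "unwrap_interval",
    "circular_distance",
]


# ---------------------------------------------------------------------------
# circular-interval arithmetic
# ---------------------------------------------------------------------------

def interval_length(start: int, end: int, genome_length: int) -> int:
    """Length of a circular half-open interval; ``start == end`` is empty."""
    return (end - start) % genome_length


def unwrap_interval(start: int, end: int, genome_length: int) -> list[tuple[int, int]]:
    """Split a possibly origin-wrapping interval into linear pieces."""
    if start < 0 or start >= genome_length:
        raise ValueError(f"start {start} outside [0, {genome_length})")
    if start <= end:
        return [(start, end)]
    return [(start, genome_length), (0, end)]


def interval_contains(start: int, end: int, pos: int, genome_length: int) -> bool:
    """Whether circular interval [start, end) contains position ``pos``."""
    return (pos - start) % genome_length < interval_length(start, end, genome_length)


def intervals_overlap_length(
    a: tuple[int, int], b: tuple[int, int], genome_length: int
) -> int:
    """Number of nucleotides shared by two circular half-open intervals."""
    total = 0
    for sa, ea in unwrap_interval(a[0], a[1], genome_length):
        for sb, eb in unwrap_interval(b[0], b[1], genome_length):
            total += max(0, min(ea, eb) - max(sa, sb))
    return total


def circular_distance(a: int, b: int, genome_length: int) -> int:
    """Shortest distance between two positions on the circle."""
    d = (a - b) % genome_length
    return min(d, genome_length - d)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA molecule (e.g. a plastome)."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        seq = self.sequence.upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Circular slice [start, end); ``start > end`` wraps the origin."""
        L = self.length
        start %= L
        end %= L
        if start <= end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    def rotate(self, offset: int) -> "CircularGenome":
        """Same molecule with the origin moved to ``offset``."""
        off = offset % self.length
        return CircularGenome(self.id, self.sequence[off:] + self.sequence[:off])


@dataclass(frozen=True)
class Gene:
    name: str
    start: int  # 0-based half-open, may wrap (start > end)
    end: int
    strand: str = "+"
    category: str = "other"  # photosynthesis | genetic_system | other

    def atg_position(self) -> int:
        """Genome coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Intron:
    parent: str
    start: int
    end: int


@dataclass(frozen=True)
class Operon:
    name: str
    members: tuple[str, ...]
    promoter_position: int | None = None


@dataclass
class Annotation:
    """Gene/intron/operon annotation on a circular genome."""

    genes: list[Gene] = field(default_factory=list)
    introns: list[Intron] = field(default_factory=list)
    operons: list[Operon] = field(default_factory=list)
    genome_length: int = 0

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError("gene names must be unique")
        by_name = {g.name: g for g in self.genes}
        for intron in self.introns:
            if intron.parent not in by_name:
                raise ValueError(f"intron parent {intron.parent!r} not annotated")
            g = by_name[intron.parent]
            L = self.genome_length
            if L:
                glen = interval_length(g.start, g.end, L)
                off = (intron.start - g.start) % L
                if off + interval_length(intron.start, intron.end, L) > glen:
                    raise ValueError(
                        f"intron [{intron.start},{intron.end}) outside parent {g.name}"
                    )

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def gene_introns(self, name: str) -> list[Intron]:
        return [i for i in self.introns if i.parent == name]

    def exonic_intervals(self, name: str) -> list[tuple[int, int]]:
        """ORF nucleotides of a gene: its span minus its introns (linearized)."""
        g = self.gene(name)
        L = self.genome_length
        # work in unwrapped offsets relative to gene start
        glen = interval_length(g.start, g.end, L)
        cuts = sorted(
            ((i.start - g.start) % L, (i.start - g.start) % L + interval_length(i.start, i.end, L))
            for i in self.gene_introns(name)
        )
        pieces, pos = [], 0
        for cs, ce in cuts:
            if cs > pos:
                pieces.append((pos, cs))
            pos = max(pos, ce)
        if pos < glen:
            pieces.append((pos, glen))
        return [((g.start + s) % L, (g.start + e - 1) % L + 1) for s, e in pieces]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> CircularGenome:
    """Read a single-record FASTA into a :class:`CircularGenome`.

    The sequence is uppercased; a multi-record file is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single FASTA record, found {len(records)}")
    rec = records[0]
    return CircularGenome(id=rec.id, sequence=str(rec.seq))


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, genome: CircularGenome) -> Annotation:
    """Read gene/intron/operon features from GFF3 (1-based inclusive) into the
    internal 0-based half-open convention."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    genes: list[Gene] = []
    introns: list[Intron] = []
    operons: list[Operon] = []
    for f in db.all_features():
        if f.end > genome.length:
            raise ValueError(
                f"feature {f.id or f.featuretype} end {f.end} beyond genome "
                f"length {genome.length}"
            )
        start, end = f.start - 1, f.end  # 1-based inclusive -> 0-based half-open
        if f.featuretype == "gene":
            name = f.attributes.get("ID", [f.id])[0]
            category = f.attributes.get("category", ["other"])[0]
            genes.append(Gene(name, start, end, f.strand or "+", category))
        elif f.featuretype == "intron":
            parents = f.attributes.get("Parent", [])
            if not parents:
                raise ValueError(f"intron at {f.start}-{f.end} has no Parent")
            introns.append(Intron(parents[0], start, end))
        elif f.featuretype == "operon":
            # GFF3 attribute values are comma-separated multi-values; accept
            # either a pre-split list or a single joined string
            raw_members = f.attributes.get("members", [])
            members = tuple(m for item in raw_members for m in item.split(","))
            prom = f.attributes.get("promoter", [None])[0]
            operons.append(
                Operon(
                    f.attributes.get("ID", [f.id])[0],
                    tuple(m for m in members if m),
                    int(prom) - 1 if prom is not None else None,
                )
            )
    return Annotation(genes=genes, introns=introns, operons=operons,
                      genome_length=genome.length)


def write_gff3(annotation: Annotation, genome_id: str, path: str | Path) -> None:
    """Write the annotation back out as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [genome_id, "plastotile", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".",
                     f"ID={g.name};category={g.category}"]
                ) + "\n"
            )
        for i in annotation.introns:
            fh.write(
                "\t".join(
                    [genome_id, "plastotile", "intron", str(i.start + 1), str(i.end),
                     ".", annotation.gene(i.parent).strand, ".",
                     f"ID=intron_{i.parent}_{i.start};Parent={i.parent}"]
                ) + "\n"
            )
        for op in annotation.operons:
            if not op.members:
                continue
            starts = [annotation.gene(m).start for m in op.members]
            ends = [annotation.gene(m).end for m in op.members]
            attrs = f"ID={op.name};members={','.join(op.members)}"
            if op.promoter_position is not None:
                attrs += f";promoter={op.promoter_position + 1}"
            fh.write(
                "\t".join(
                    [genome_id, "plastotile", "operon", str(min(starts) + 1),
                     str(max(ends)), ".",
                     annotation.gene(op.members[0]).strand, ".", attrs]
                ) + "\n"
            )


# ---------------------------------------------------------------------------
# BED / WIG / TSV
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Iterable[tuple],
    path: str | Path,
    genome_length: int,
    chrom: str = "genome",
) -> None:
    """Write intervals as BED6.

    Each interval is ``(start, end, name)`` or ``(start, end, name, score,
    strand)`` in internal circular coordinates.  Origin-wrapping intervals are
    split into two records that share their name.
    """
    with open(path, "w") as fh:
        for item in intervals:
            start, end, name = item[0], item[1], item[2]
            score = item[3] if len(item) > 3 else 0
            strand = item[4] if len(item) > 4 else "+"
            for s, e in unwrap_interval(start, end, genome_length):
                if s == e:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[int, int, str, float, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(
                (int(parts[1]), int(parts[2]),
                 parts[3] if len(parts) > 3 else ".",
                 float(parts[4]) if len(parts) > 4 else 0.0,
                 parts[5] if len(parts) > 5 else "+")
            )
    return out


def write_wig(
    values: Sequence[float],
    start: int,
    step: int,
    path: str | Path,
    chrom: str = "genome",
    genome_length: int | None = None,
    name: str = "track",
) -> None:
    """Write a fixed-step track (WIG is 1-based).

    ``start`` is the internal 0-based position of the first value.  If the
    track runs past the origin of a circular genome, a second ``fixedStep``
    block is emitted for the wrapped tail.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        if genome_length is not None:
            n_before = min(len(values), (genome_length - start + step - 1) // step)
        else:
            n_before = len(values)
        fh.write(f"fixedStep chrom={chrom} start={start + 1} step={step} span={step}\n")
        for v in values[:n_before]:
            fh.write(f"{v:.6g}\n")
        tail = values[n_before:]
        if len(tail) and genome_length is not None:
            wrap_start = (start + n_before * step) % genome_length
            fh.write(
                f"fixedStep chrom={chrom} start={wrap_start + 1} step={step} span={step}\n"
            )
            for v in tail:
                fh.write(f"{v:.6g}\n")


def write_tsv(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
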