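"""Genome, gene-annotation and regulatory-interval containers.

All coordinates are 0-based, half-open.  Gene annotations carry an
``orf_start`` — the strand-aware translation start used to anchor 2-kb
promoter windows — in addition to the gene span.  Chromatin states follow
the five-colour model (red/yellow active, blue Polycomb, green/black
repressive) and tile each chromosome without gaps or overlaps.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHROMATIN_STATES = ("red", "yellow", "blue", "green", "black")
PRE_CLASSES = ("intergenic", "enhancer", "promoter", "other")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: span, strand, and the translation start anchoring promoters."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    orf_start: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if not self.start <= self.orf_start <= self.end:
            raise ValueError(f"{self.gene_id}: orf_start outside gene span")

    @property
    def tss(self) -> int:
        """5' end of the gene (start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PRERecord:
    """A predicted Polycomb response element with class and confidence."""

    chrom: str
    start: int
    end: int
    pre_class: str
    confidence: float

    def __post_init__(self) -> None:
        if self.pre_class not in PRE_CLASSES:
            raise ValueError(f"unknown PRE class {self.pre_class!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class GenomeModel:
    """A small multi-chromosome genome plus its annotation layers."""

    chromosomes: list[tuple[str, int, str]]  # (name, length, sequence)
    genes: list[GeneAnnotation] = field(default_factory=list)
    chromatin_states: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "state"])
    )
    pres: list[PRERecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = self.chrom_lengths
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} exceeds chromosome bounds")
        for p in self.pres:
            if p.chrom not in lengths or p.end > lengths[p.chrom] or p.start < 0:
                raise ValueError("PRE outside chromosome bounds")

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: length for name, length, _ in self.chromosomes}

    def sequence(self, chrom: str) -> str:
        for name, _, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.gene_id, g.chrom, g.strand, g.start, g.end, g.orf_start)
                for g in self.genes
            ],
            columns=["gene_id", "chrom", "strand", "start", "end", "orf_start"],
        )

    def pres_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.chrom, p.start, p.end, p.pre_class, p.confidence) for p in self.pres],
            columns=["chrom", "start", "end", "pre_class", "confidence"],
        )

    # ------------------------------------------------------------------ I/O
    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, _, seq in self.chromosomes
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        """GFF3 is 1-based closed; orf_start is carried as an attribute."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, length, _ in self.chromosomes:
                fh.write(f"##sequence-region {name} 1 {length}\n")
            for g in self.genes:
                attrs = f"ID={g.gene_id};orf_start={g.orf_start}"
                fh.write(
                    f"{g.chrom}\tdamidreg\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    def write_states_bed(self, path: str | Path) -> None:
        self.chromatin_states.to_csv(path, sep="\t", header=False, index=False)

    def write_pres_bed(self, path: str | Path) -> None:
        self.pres_frame().to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> list[tuple[str, int, str]]:
    """Read chromosomes from FASTA as (name, length, sequence) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        out.append((rec.id, len(seq), seq))
    return out


def intervals_frame(intervals: Iterable[tuple[str, int, int]]) -> pd.DataFrame:
    """Normalise an iterable of (chrom, start, end) into a sorted frame."""
    df = pd.DataFrame(list(intervals), columns=["chrom", "start", "end"])
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"malformed intervals (start >= end): {df[bad].head()}")
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def state_at(states: pd.DataFrame, chrom: str, pos: int) -> str | None:
    """Chromatin-state label covering one position, or None if uncovered."""
    sub = states[states["chrom"] == chrom]
    if sub.empty:
        return None
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    if idx < 0 or pos >= ends[idx]:
        return None
    return str(sub["state"].iloc[idx])
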