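"""Genome containers and plain-text genomics IO (FASTA, FASTQ, BED, TSV)."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import seq as sq


@dataclass(frozen=True)
class Gene:
    """BED-style gene interval: 0-based half-open, strand '+' or '-'."""

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"zero/negative-length gene {self.gene_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CircularGenome:
    """A (possibly circular) genome with BED-style annotation.

    The unit of both simulation and assembly: organelle genomes carry
    ``circular=True``; the 45S repeat unit and unfinished contigs are linear.
    """

    id: str
    sequence: str
    circular: bool = True
    annotation: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        for g in self.annotation:
            if g.start < 0 or g.end > len(self.sequence):
                raise ValueError(f"gene {g.gene_id} outside [0, {len(self.sequence)})")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self):
        return sq.encode(self.sequence)

    def gene(self, gene_id: str) -> Gene:
        for g in self.annotation:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_sequence(self, gene_id: str) -> str:
        g = self.gene(gene_id)
        s = self.sequence[g.start : g.end]
        return s if g.strand == "+" else sq.revcomp(s)


# ---------------------------------------------------------------------------
# FASTA / FASTQ / BED
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as 60-column wrapped FASTA."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def genome_fasta_header(g: CircularGenome) -> str:
    return f"{g.id} circular={'true' if g.circular else 'false'}"


def write_genomes_fasta(path: str | Path, genomes: Sequence[CircularGenome]) -> None:
    recs = [
        SeqRecord(Seq(g.sequence), id=g.id, description=f"circular={'true' if g.circular else 'false'}")
        for g in genomes
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Phred+33 FASTQ with a fixed quality character for simulated bases."""
    with open(path, "w") as fh:
        for name, s in reads:
            fh.write(f"@{name}\n{s}\n+\n{quality_char * len(s)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            s = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((h[1:].strip().split()[0], s))
    return out


def write_bed(path: str | Path, chrom: str, genes: Sequence[Gene]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_bed(path: str | Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            genes.append(Gene(parts[3], int(parts[1]), int(parts[2]), parts[5].strip()))
    return genes


def fasta_bytes(records: Iterable[tuple[str, str]]) -> bytes:
    buf = io.StringIO()
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(recs, buf, "fasta")
    return buf.getvalue().encode()
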