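"""Sequence I/O and circular-coordinate arithmetic.

All coordinates in this package are 1-based and inclusive on the
virion-sense strand. Antisense features are written ``start > end``
("read descending"), the convention used for ambisense circular ssDNA
virus genomes (e.g. a replicase ORF at nt 1541-846). Regions may wrap
the origin of a circular genome.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq

VIRION_SENSE = "+"
ANTISENSE = "-"

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when a sequence file violates the expected format/alphabet."""


@dataclass(frozen=True)
class CircularGenome:
    """A named DNA sequence with explicit topology.

    The sequence is stored uppercased over the alphabet {A, C, G, T, N}.
    """

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"{self.id}: topology must be circular or linear")
        bad = next((i for i, c in enumerate(self.seq) if c not in _VALID), None)
        if bad is not None:
            raise ParseError(
                f"record {self.id!r}: invalid character {self.seq[bad]!r} "
                f"at offset {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class GenomeRegion:
    """A 1-based inclusive span on a (possibly circular) genome.

    ``strand == VIRION_SENSE`` regions read ascending from start_nt to
    end_nt (wrapping past the origin when start_nt > end_nt on a circular
    genome). ``strand == ANTISENSE`` regions read *descending* from
    start_nt to end_nt on virion-sense numbering, so start_nt > end_nt is
    the normal, non-wrapping case.
    """

    start_nt: int
    end_nt: int
    strand: str = VIRION_SENSE

    def __post_init__(self) -> None:
        if self.start_nt < 1 or self.end_nt < 1:
            raise ValueError("coordinates are 1-based; got "
                             f"({self.start_nt}, {self.end_nt})")
        if self.strand not in (VIRION_SENSE, ANTISENSE):
            raise ValueError(f"bad strand {self.strand!r}")

    def length(self, genome_len: int) -> int:
        if self.strand == VIRION_SENSE:
            return (self.end_nt - self.start_nt) % genome_len + 1
        return (self.start_nt - self.end_nt) % genome_len + 1


def normalize_seq(raw: str, *, record_id: str = "?") -> str:
    """Uppercase, convert U->T, and validate the alphabet."""
    seq = raw.upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in _VALID:
            raise ParseError(
                f"record {record_id!r}: invalid character {c!r} at offset {i + 1}"
            )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters for revcomp: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(genome: CircularGenome, new_start: int) -> CircularGenome:
    """Return the genome re-linearized to begin at ``new_start``.

    Only defined for circular genomes; rotate(g, 1) is the identity.
    """
    if not genome.is_circular:
        raise ValueError(f"{genome.id}: cannot rotate a linear genome")
    L = len(genome)
    if not 1 <= new_start <= L:
        raise ValueError(f"{genome.id}: new_start {new_start} outside 1..{L}")
    i = new_start - 1
    return replace(genome, seq=genome.seq[i:] + genome.seq[:i])


def region_seq(genome: CircularGenome, region: GenomeRegion) -> str:
    """Extract the reading-direction sequence of a region.

    Antisense regions are returned reverse-complemented (i.e. in their
    own coding orientation).
    """
    L = len(genome)
    if region.strand == VIRION_SENSE:
        s, e = region.start_nt, region.end_nt
    else:
        s, e = region.end_nt, region.start_nt
    if s <= e:
        sub = genome.seq[s - 1:e]
    else:
        if not genome.is_circular:
            raise ValueError("wrapping region on a linear genome")
        sub = genome.seq[s - 1:] + genome.seq[:e]
    return sub if region.strand == VIRION_SENSE else revcomp(sub)


def wrap_position(pos: int, genome_len: int) -> int:
    """Map any integer onto 1..genome_len (circular arithmetic)."""
    return (pos - 1) % genome_len + 1


def read_fasta(path: Union[str, Path, io.TextIOBase],
               topology: str = "circular") -> list[CircularGenome]:
    """Read a FASTA file into a list of :class:`CircularGenome`.

    Sequences are uppercased, U is converted to T, and any character
    outside {A, C, G, T, N, U} raises :class:`ParseError` naming the
    record and offset. Record order is preserved.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return [
        CircularGenome(r.id, normalize_seq(str(r.seq), record_id=r.id), topology)
        for r in records
    ]


def write_fasta(genomes: Iterable[CircularGenome],
                path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), 70):
                fh.write(g.seq[i:i + 70] + "\n")


def read_genbank(path: Union[str, Path],
                 topology: str = "circular") -> list[CircularGenome]:
    """Read GenBank flat files (sequence only; features are ignored)."""
    records = list(SeqIO.parse(path, "genbank"))
    if not records:
        raise ParseError(f"{path}: no GenBank records found")
    return [
        CircularGenome(r.id, normalize_seq(str(r.seq), record_id=r.id), topology)
        for r in records
    ]
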