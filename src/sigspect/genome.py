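"""Local reference-genome access for trinucleotide context lookup.

Sequences come from a local FASTA file rather than a remote genome
service, which keeps spectrum construction deterministic and offline.
Soft-masked (lowercase) bases are uppercased and counted; any N inside a
trinucleotide window excludes that site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .maf import normalize_chrom

_VALID_BASES = frozenset("ACGTN")


class UnknownContigError(KeyError):
    """Lookup of a contig the genome does not contain (distinct from a
    position whose context is simply unavailable)."""


@dataclass(frozen=True)
class GenomeSequence:
    """Uppercase contig sequences keyed by normalized chromosome name."""

    contigs: dict[str, str] = field(default_factory=dict)

    def contig(self, chrom: str) -> str:
        name = normalize_chrom(chrom)
        try:
            return self.contigs[name]
        except KeyError:
            raise UnknownContigError(name) from None

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.contigs


def load_fasta(path: str | Path) -> GenomeSequence:
    """Load a (multi-contig) FASTA into memory.

    Contig names are the first whitespace-delimited token of each header,
    normalized like MAF chromosome names. Duplicate contig names and empty
    sequences are errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = normalize_chrom(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for contig {rec.id!r}")
        if name in contigs:
            raise ValueError(f"{path}: duplicate contig name {name!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: contig {name!r} contains invalid characters {sorted(bad)}"
            )
        contigs[name] = seq
    if not contigs:
        raise ValueError(f"{path}: no contigs found")
    return GenomeSequence(contigs)


def get_trinucleotide(
    genome: GenomeSequence, chrom: str, pos: int
) -> str | None:
    """Bases at ``pos - 1, pos, pos + 1`` (1-based), or None when the
    position touches a contig boundary or the window contains an N.

    Raises :class:`UnknownContigError` for a contig absent from the genome.
    """
    seq = genome.contig(chrom)
    if pos <= 1 or pos >= len(seq):
        return None
    tri = seq[pos - 2 : pos + 1]
    if "N" in tri:
        return None
    return tri
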