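"""Reading and writing somatic variant calls in MAF (Mutation Annotation
Format), GDC dialect.

Only the six columns the spectrum pipeline needs are mapped
(Chromosome, Start_Position, Reference_Allele, Tumor_Seq_Allele2,
Variant_Type, Tumor_Sample_Barcode); all other columns are ignored on read
and omitted on write. Positions are 1-based throughout. Chromosome names
are normalized to carry a ``chr`` prefix so MAFs and FASTAs that disagree
("1" vs "chr1") interoperate.
"""

from __future__ import annotations

import csv
import gzip
import io
import warnings
from pathlib import Path
from typing import Iterable, NamedTuple

VARIANT_TYPES = frozenset({"SNP", "INS", "DEL", "DNP", "TNP", "ONP"})
ALLELE_ALPHABET = frozenset("ACGT-")

REQUIRED_COLUMNS = (
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Tumor_Sample_Barcode",
)

_GZIP_MAGIC = b"\x1f\x8b"


class MafSchemaError(ValueError):
    """The MAF header is missing a required column."""


class MafRowError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class MafRecord(NamedTuple):
    """One somatic variant call with sample attribution."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_type: str
    sample_id: str

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.sample_id:
            raise ValueError("sample_id is empty")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.variant_type!r}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or any(c not in ALLELE_ALPHABET for c in allele):
                raise ValueError(f"invalid allele {allele!r}")
        is_snv = (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele != "-"
            and self.alt_allele != "-"
            and self.ref_allele != self.alt_allele
        )
        if (self.variant_type == "SNP") != is_snv:
            raise ValueError(
                f"variant type {self.variant_type} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele}"
            )


def normalize_chrom(name: str) -> str:
    """Normalize a contig name to the ``chr``-prefixed form."""
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


def _open_text(path: str | Path):
    # gzip is detected by magic bytes, never by extension
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="utf-8", newline="")
    return open(path, "rt", encoding="utf-8", newline="")


def read_maf(path: str | Path, strict: bool = True) -> list[MafRecord]:
    """Read a MAF file (plain or gzip) into a list of records, row order
    preserved.

    Comment lines starting with ``#`` before the header are skipped. In
    strict mode (default) any malformed data row raises :class:`MafRowError`
    with its line number; in lenient mode malformed rows are skipped and a
    single summary warning reports how many.
    """
    records: list[MafRecord] = []
    skipped = 0
    with _open_text(path) as handle:
        line_number = 0
        header: list[str] | None = None
        for line in handle:
            line_number += 1
            if line.startswith("#"):
                continue
            header = line.rstrip("\r\n").split("\t")
            break
        if header is None:
            raise MafSchemaError(f"{path}: no header line found")
        column_pos: dict[str, int] = {}
        for col in REQUIRED_COLUMNS:
            try:
                column_pos[col] = header.index(col)
            except ValueError:
                raise MafSchemaError(
                    f"{path}: missing required MAF column {col!r}"
                ) from None
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            line_number += 1
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                records.append(_parse_row(row, column_pos, line_number))
            except MafRowError:
                if strict:
                    raise
                skipped += 1
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} malformed MAF row(s) in lenient mode",
            stacklevel=2,
        )
    return records


def _parse_row(
    row: list[str], column_pos: dict[str, int], line_number: int
) -> MafRecord:
    try:
        fields = {col: row[idx] for col, idx in column_pos.items()}
    except IndexError:
        raise MafRowError("too few columns", line_number) from None
    try:
        pos = int(fields["Start_Position"])
    except ValueError:
        raise MafRowError(
            f"unparsable Start_Position {fields['Start_Position']!r}", line_number
        ) from None
    try:
        record = MafRecord(
            chrom=normalize_chrom(fields["Chromosome"]),
            pos=pos,
            ref_allele=fields["Reference_Allele"].upper(),
            alt_allele=fields["Tumor_Seq_Allele2"].upper(),
            variant_type=fields["Variant_Type"].upper(),
            sample_id=fields["Tumor_Sample_Barcode"],
        )
        record.validate()
    except ValueError as exc:
        raise MafRowError(str(exc), line_number) from None
    return record


def write_maf(records: Iterable[MafRecord], path: str | Path) -> None:
    """Write records as a GDC-dialect TSV; ``read_maf`` inverts it exactly."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        _write_maf_handle(records, handle)


def _write_maf_handle(records: Iterable[MafRecord], handle: io.TextIOBase) -> None:
    handle.write("\t".join(REQUIRED_COLUMNS) + "\n")
    for record in records:
        record.validate()
        handle.write(
            "\t".join(
                (
                    record.chrom,
                    str(record.pos),
                    record.ref_allele,
                    record.alt_allele,
                    record.variant_type,
                    record.sample_id,
                )
            )
            + "\n"
        )
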