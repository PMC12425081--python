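"""SBS96 classification of SNVs and per-sample spectrum matrices.

Every SNP record either increments exactly one of the 96 channels or is
excluded for a recorded reason (contig-boundary context, N in the window,
or the genome base disagreeing with the MAF reference allele, which
signals a genome-build mismatch and is never reinterpreted). Per sample,
classified + excluded always equals the number of SNP records supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .channels import CHANNEL_INDEX, channel_label
from .genome import GenomeSequence, get_trinucleotide
from .maf import MafRecord

# exclusion bookkeeping; NON_SNV records are reported but are not SNP records,
# so they do not enter the classified + excluded conservation identity
REASON_NON_SNV = "non_snv"
REASON_BOUNDARY = "boundary_or_n"
REASON_REF_MISMATCH = "ref_mismatch"
EXCLUSION_REASONS = (REASON_NON_SNV, REASON_BOUNDARY, REASON_REF_MISMATCH)


def _classify(record: MafRecord, genome: GenomeSequence) -> tuple[str | None, str | None]:
    """(channel label, None) on success; (None, reason) otherwise."""
    if record.variant_type != "SNP":
        return None, REASON_NON_SNV
    tri = get_trinucleotide(genome, record.chrom, record.pos)
    if tri is None:
        return None, REASON_BOUNDARY
    if tri[1] != record.ref_allele:
        return None, REASON_REF_MISMATCH
    return channel_label(record.ref_allele, record.alt_allele, tri), None


def classify_sbs96(record: MafRecord, genome: GenomeSequence) -> str | None:
    """SBS96 channel label for a record, or None when it cannot be
    classified (non-SNV, boundary/N context, or reference mismatch).

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand before labeling (COSMIC convention).
    """
    label, _ = _classify(record, genome)
    return label


@dataclass
class SpectrumMatrix:
    """Per-sample SBS96 mutation spectra.

    Attributes
    ----------
    sample_ids
        Samples in first-appearance order in the input records.
    counts
        ``(n_samples, 96)`` nonnegative integer matrix in canonical
        channel order.
    excluded
        Per-sample count of SNP records dropped (boundary/N or reference
        mismatch); non-SNV records are tallied separately in
        ``excluded_by_reason``.
    excluded_by_reason
        Per-sample dict mapping exclusion reason to count.
    """

    sample_ids: list[str]
    counts: np.ndarray
    excluded: np.ndarray
    excluded_by_reason: list[dict[str, int]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.excluded = np.asarray(self.excluded, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), 96):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x 96 channels"
            )
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]


def build_spectra(
    records: Iterable[MafRecord],
    genome: GenomeSequence,
    dedup: bool = False,
) -> SpectrumMatrix:
    """Assemble a spectrum matrix from variant records.

    One row per distinct sample in first-appearance order; samples whose
    records all fail classification are kept as all-zero rows. Duplicate
    records (same sample, position and alleles) are counted every time
    they occur, with a warning, unless ``dedup`` collapses them.
    """
    sample_order: dict[str, int] = {}
    rows: list[np.ndarray] = []
    excluded: list[int] = []
    reasons: list[dict[str, int]] = []
    seen: set[tuple] = set()
    duplicates = 0

    for record in records:
        idx = sample_order.get(record.sample_id)
        if idx is None:
            idx = len(rows)
            sample_order[record.sample_id] = idx
            rows.append(np.zeros(96, dtype=np.int64))
            excluded.append(0)
            reasons.append({})
        key = (
            record.sample_id,
            record.chrom,
            record.pos,
            record.ref_allele,
            record.alt_allele,
        )
        if key in seen:
            duplicates += 1
            if dedup:
                continue
        else:
            seen.add(key)
        label, reason = _classify(record, genome)
        if label is not None:
            rows[idx][CHANNEL_INDEX[label]] += 1
        else:
            reasons[idx][reason] = reasons[idx].get(reason, 0) + 1
            if reason != REASON_NON_SNV:
                excluded[idx] += 1

    if duplicates and not dedup:
        warnings.warn(
            f"{duplicates} duplicate record(s) counted multiple times "
            "(pass dedup=True to collapse)",
            stacklevel=2,
        )
    n = len(rows)
    return SpectrumMatrix(
        sample_ids=list(sample_order),
        counts=np.vstack(rows) if n else np.zeros((0, 96), dtype=np.int64),
        excluded=np.asarray(excluded, dtype=np.int64),
        excluded_by_reason=reasons,
    )


def total_mutations(spectrum: SpectrumMatrix, sample_id: str) -> int:
    """Total classified mutations (row sum) for one sample."""
    return int(spectrum.row(sample_id).sum())


def sample_totals(spectrum: SpectrumMatrix) -> dict[str, int]:
    """Mapping sample id -> total classified mutations."""
    sums = spectrum.counts.sum(axis=1)
    return {s: int(t) for s, t in zip(spectrum.sample_ids, sums)}
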