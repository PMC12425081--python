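"""Synthetic genomes, signature catalogs, and ground-truth cohorts.

Everything the pipeline consumes can be generated offline with explicit
seeds: a toy genome (i.i.d. uniform bases), a Dirichlet-drawn signature
catalog, and a cohort of MAF records planted so that every record
classifies back to a channel drawn from its sample's true signature
mixture. About half of planted mutations land on purine-reference
positions (the genome strand carries the purine partner of the channel's
pyrimidine context), deliberately exercising the strand-symmetry path.

The generator emulates the mixture model behind signature refitting —
channel counts are i.i.d. draws from a convex combination of reference
profiles — and none of the confounders of real tumor genomes (GC content,
regional mutation-rate covariates, sequencing error, subclonality).

All randomness flows through one integer seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .channels import BASES, SBS96_LABELS, channel_context, revcomp
from .fitting import SignatureCatalog
from .genome import GenomeSequence
from .maf import MafRecord

# the 32 pyrimidine-centred trinucleotide contexts, in channel order
PYRIMIDINE_CONTEXTS: tuple[str, ...] = tuple(
    dict.fromkeys(channel_context(label) for label in SBS96_LABELS)
)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i

_CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(PYRIMIDINE_CONTEXTS)}


def _normalized_context_codes(seq: str) -> np.ndarray:
    """Per interior position: index of the pyrimidine-normalized context
    in PYRIMIDINE_CONTEXTS, or -1 where the window touches an N."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    valid = (a < 4) & (b < 4) & (c < 4)
    tri = 16 * a.astype(np.int32) + 4 * b + c
    lookup = np.full(64, -1, dtype=np.int32)
    for code in range(64):
        bases = BASES[code // 16] + BASES[(code // 4) % 4] + BASES[code % 4]
        ctx = bases if bases[1] in "CT" else revcomp(bases)
        lookup[code] = _CONTEXT_INDEX[ctx]
    out = np.where(valid, lookup[tri % 64], -1)
    return out.astype(np.int32)


def index_contexts(genome: GenomeSequence) -> dict[str, list[tuple[str, int]]]:
    """Map each pyrimidine-centred context to every (chrom, 1-based pos)
    in the genome whose normalized trinucleotide matches it."""
    index: dict[str, list[tuple[str, int]]] = {ctx: [] for ctx in PYRIMIDINE_CONTEXTS}
    for chrom, seq in genome.contigs.items():
        if len(seq) < 3:
            continue
        ctx_codes = _normalized_context_codes(seq)
        for code, ctx in enumerate(PYRIMIDINE_CONTEXTS):
            positions = np.nonzero(ctx_codes == code)[0] + 2  # 1-based middle
            index[ctx].extend((chrom, int(p)) for p in positions)
    return index


def gen_genome(length: int, seed: int) -> GenomeSequence:
    """Single-contig toy genome of i.i.d. uniform bases.

    For length >= 10,000 the sequence is guaranteed to contain every one
    of the 32 pyrimidine-centred trinucleotides (regenerated with an
    incremented sub-seed until satisfied; a uniform 10 kb sequence
    virtually always does on the first draw).
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        if length < 10_000:
            break
        present = {
            ctx
            for ctx, hits in index_contexts(
                GenomeSequence({"chr1": seq})
            ).items()
            if hits
        }
        if len(present) == 32:
            break
    return GenomeSequence({"chr1": seq})


def gen_catalog(k: int, concentration: float, seed: int) -> SignatureCatalog:
    """k signatures drawn i.i.d. from a symmetric Dirichlet over the 96
    channels; small concentrations give sparse, spiky profiles."""
    if k < 1:
        raise ValueError("need at least one signature")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(96, concentration), size=k)
    return SignatureCatalog(
        signature_ids=[f"SigSim{i + 1}" for i in range(k)],
        profiles=profiles,
    )


@dataclass
class CohortTruth:
    """A simulated cohort with its generating ground truth.

    ``true_exposures`` are absolute (mutation-count units): the Dirichlet
    mixture weights times mutations per sample, so each row sums to the
    sample's SNP count.
    """

    genome: GenomeSequence
    catalog: SignatureCatalog
    sample_ids: list[str]
    true_exposures: np.ndarray  # samples x signatures, absolute
    maf: list[MafRecord]
    seed: int

    @property
    def true_relative(self) -> np.ndarray:
        totals = self.true_exposures.sum(axis=1, keepdims=True)
        return self.true_exposures / totals


def gen_cohort(
    genome: GenomeSequence,
    catalog: SignatureCatalog,
    n_samples: int,
    mutations_per_sample: int,
    seed: int,
) -> CohortTruth:
    """Simulate a cohort of MAF records from a signature mixture model.

    Per sample: mixture weights are drawn from a flat Dirichlet over the
    catalog; each mutation draws a signature by weight, a channel from
    that signature's profile, and a uniformly random genome position whose
    pyrimidine-normalized context matches the channel. Ref/alt alleles are
    emitted on the genome's literal strand (reverse-complemented where the
    genome carries the purine partner).
    """
    if n_samples < 1 or mutations_per_sample < 1:
        raise ValueError("need >= 1 sample and >= 1 mutation per sample")
    rng = np.random.default_rng(seed)
    k = catalog.n_signatures

    needed = {
        channel_context(SBS96_LABELS[j])
        for j in np.nonzero(catalog.profiles.sum(axis=0) > 0)[0]
    }
    index = index_contexts(genome)
    for ctx in sorted(needed):
        if not index[ctx]:
            raise ValueError(
                f"no genome position matches required context {ctx!r}"
            )
    positions = {ctx: index[ctx] for ctx in PYRIMIDINE_CONTEXTS}

    channel_ctx_code = np.array(
        [_CONTEXT_INDEX[channel_context(lab)] for lab in SBS96_LABELS]
    )
    cum_profiles = np.cumsum(catalog.profiles, axis=1)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    weights = rng.dirichlet(np.ones(k), size=n_samples)
    true_exposures = weights * mutations_per_sample
    records: list[MafRecord] = []

    for i, sample_id in enumerate(sample_ids):
        sigs = rng.choice(k, size=mutations_per_sample, p=weights[i])
        u = rng.random(mutations_per_sample)
        channels = (u[:, None] < cum_profiles[sigs]).argmax(axis=1)
        picks = rng.integers(
            0,
            [len(positions[PYRIMIDINE_CONTEXTS[channel_ctx_code[ch]]]) for ch in channels],
        )
        for ch, pick in zip(channels, picks):
            label = SBS96_LABELS[ch]
            chrom, pos = positions[channel_context(label)][pick]
            ref, alt = label[2], label[4]
            base = genome.contigs[chrom][pos - 1]
            if base != ref:  # genome carries the purine partner strand
                ref, alt = revcomp(ref), revcomp(alt)
            records.append(
                MafRecord(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_type="SNP",
                    sample_id=sample_id,
                )
            )
    return CohortTruth(
        genome=genome,
        catalog=catalog,
        sample_ids=sample_ids,
        true_exposures=true_exposures,
        maf=records,
        seed=seed,
    )


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    """Plain FASTA writer with fixed line wrapping (byte-deterministic)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        for chrom, seq in genome.contigs.items():
            handle.write(f">{chrom}\n")
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


def write_catalog_tsv(catalog: SignatureCatalog, path: str | Path) -> None:
    """COSMIC-layout catalog TSV (96 context rows, one column per
    signature, repr floats for exact round trips)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("Type\t" + "\t".join(catalog.signature_ids) + "\n")
        for j, label in enumerate(SBS96_LABELS):
            vals = "\t".join(repr(float(v)) for v in catalog.profiles[:, j])
            handle.write(f"{label}\t{vals}\n")
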