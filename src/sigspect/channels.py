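"""SBS96 channel algebra.

The 96 single-base-substitution classes are written ``X[R>A]Y`` with the
reference base R reported on the pyrimidine strand (R in {C, T}), the
alternate base A, and the immediate 5' and 3' flanking bases X and Y.
Substitutions observed with a purine reference are reverse-complemented
before classification, so every variant maps to exactly one channel.

Canonical index order (the layout COSMIC-style catalogs use): substitution
blocks C>A, C>G, C>T, T>A, T>C, T>G; within each block the 16 contexts are
ordered by 5' base then 3' base, each in A, C, G, T order.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

SBS96_LABELS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(SBS96_LABELS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def channel_label(ref: str, alt: str, trinucleotide: str) -> str:
    """Pyrimidine-normalized SBS96 label for a substitution in context.

    Parameters
    ----------
    ref, alt
        Single reference and alternate bases on the genome's literal strand.
    trinucleotide
        The three genome bases centred on the variant position; its middle
        base must equal ``ref``.

    Raises
    ------
    ValueError
        If the inputs are not a valid single-base substitution in context.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        raise ValueError(f"not a single-base substitution: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"reference and alternate are identical: {ref!r}")
    if len(trinucleotide) != 3 or any(b not in BASES for b in trinucleotide):
        raise ValueError(f"invalid trinucleotide context: {trinucleotide!r}")
    if trinucleotide[1] != ref:
        raise ValueError(
            f"context middle base {trinucleotide[1]!r} does not match ref {ref!r}"
        )
    if ref in PURINES:
        ref, alt = revcomp(ref), revcomp(alt)
        trinucleotide = revcomp(trinucleotide)
    return f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"


def channel_context(label: str) -> str:
    """The pyrimidine-strand trinucleotide context of a channel label."""
    return label[0] + label[2] + label[6]
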