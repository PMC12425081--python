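"""Build SBS96 spectra from a small MAF against a local FASTA.

Writes a five-variant MAF and a toy genome to a temp directory, converts
the calls into a per-sample 96-channel spectrum, and prints the non-zero
channels plus the exclusion bookkeeping. Every SNP either lands in exactly
one channel or is excluded for a stated reason; the insertion is reported
but never counted against the spectrum.
"""

import tempfile
from pathlib import Path

from sigspect import (
    build_spectra,
    load_fasta,
    log_count_summary,
    read_maf,
    write_maf,
    MafRecord,
    SBS96_LABELS,
)

workdir = Path(tempfile.mkdtemp())

fasta = workdir / "genome.fa"
fasta.write_text(">chr1\nTTACATGTACGCTTAGC\n")

records = [
    MafRecord("chr1", 4, "C", "A", "SNP", "patient1"),   # context ACA
    MafRecord("chr1", 7, "G", "T", "SNP", "patient1"),   # purine strand, TGT
    MafRecord("chr1", 11, "G", "A", "SNP", "patient2"),  # purine strand, CGC
    MafRecord("chr1", 1, "T", "G", "SNP", "patient2"),   # contig edge: excluded
    MafRecord("chr1", 9, "-", "TT", "INS", "patient2"),  # not an SNV
]
maf_path = workdir / "calls.maf"
write_maf(records, maf_path)

genome = load_fasta(fasta)
spectra = build_spectra(read_maf(maf_path), genome)

for i, sample in enumerate(spectra.sample_ids):
    hits = {
        SBS96_LABELS[j]: int(c)
        for j, c in enumerate(spectra.counts[i]) if c
    }
    print(f"{sample}: {hits}  excluded={int(spectra.excluded[i])} "
          f"({spectra.excluded_by_reason[i]})")

summary = log_count_summary(spectra, {s: "demo" for s in spectra.sample_ids})
print(f"log10 mutation-count summary: {summary[0]}")
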