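# Methods

## Spectrum construction

Variants arrive as GDC-dialect MAF rows; only the six columns needed for
spectra are mapped (Chromosome, Start_Position, Reference_Allele,
Tumor_Seq_Allele2, Variant_Type, Tumor_Sample_Barcode). Positions are
1-based end to end. Chromosome names are normalized to a `chr` prefix on
both the MAF and FASTA sides, since the two formats disagree in the wild.
Gzip input is detected by magic bytes, never by file extension. Malformed
rows are a hard error by default (`strict`); `lenient` mode skips them
with a counted warning — silent row loss would corrupt spectra, so
skipping is never the default.

Trinucleotide context comes from a local FASTA rather than a remote
genome service, which keeps classification deterministic, offline and
testable; the package is genome-build-agnostic (use whatever FASTA the
calls were made against). Soft-masked lowercase bases are uppercased and
counted, following signature-tool convention. A site is excluded when its
window touches a contig boundary or contains an N.

Classification follows the COSMIC pyrimidine convention: a purine
reference is reverse-complemented together with its alternate and
context, so each SNV maps to exactly one of 96 channels in the canonical
block order (C>A, C>G, C>T, T>A, T>C, T>G; contexts by 5' then 3' base in
A,C,G,T order). When the genome base disagrees with the MAF reference
allele the record is excluded and counted, never reinterpreted: a
mismatch signals a genome-build mix-up, and corrupting a channel is worse
than dropping a record. Duplicate records are counted each time they
occur (merged-caller MAFs can legitimately repeat; the simulator also
produces genuine position collisions) with a warning, and an optional
`dedup` flag collapses them. Per sample, classified + excluded always
equals the number of SNP records supplied; non-SNV records are reported
separately and never enter that identity.

## NNLS refitting

Exposures solve `min ‖v − Sᵀe‖², e ≥ 0` via scipy's Lawson–Hanson
active-set solver. The contract is stated through the KKT conditions
(gradient ≈ 0 on the support, ≥ 0 off it, tolerance 1e-8 on unit-scale
problems) rather than a named algorithm, and the test suite certifies
them together with a brute-force shrinking-box grid-search oracle.
`r_norm` is the **sum** of squared residuals, not its root, and is
exported under that name. Spectra are fitted as raw counts: the problem
is scale-equivariant, so relative exposures are identical under any
prior normalization. No sparsity penalty or exposure pruning is applied —
the refit is plain NNLS; a display threshold exists but defaults to off
(0). Catalog columns that drift from sum 1 at rounding level are
renormalized on load with a warning instead of rejected, because
published catalogs carry rounding error.

## Clustering

Cosine distance of nonnegative vectors lies in [0, 1]; an all-zero row is
an error naming the sample (its direction is undefined). UPGMA is
implemented with the size-weighted Lance–Williams update, which is
algebraically identical to the unweighted mean over all cross pairs of
original leaf distances; the test oracle recomputes those means from
scratch each step. Where the method itself is silent, determinism is
imposed by convention: ties on the minimum distance merge the pair whose
(smaller, larger) cluster-representative indices are lexicographically
least (a cluster's representative is its smallest original leaf index),
and the child containing the smaller original index is placed left, so
heatmap leaf orders are reproducible. Node annotations read the
"similarity between the two clusters" as the cluster-level average-
linkage value (1 − merge distance), not a single-pair or centroid
similarity. Trees serialize to Newick (branch length = parent height −
child height) and to JSON with all annotations; computing a visual
layout (force-directed or otherwise) is explicitly out of scope — the
JSON carries everything a renderer needs. Double clustering runs UPGMA
independently on rows and on columns of the exposure matrix; column
totals are the per-signature exposure sums across the cohort.

## Summaries and export

The mutation-count boxplot summary uses log base 10 (stated in the output
header) and type-7 linear interpolation for quartiles; any fixed rule
works if declared, and these are the common defaults. Zero-mutation
samples are excluded with a warning before the log. CSV output is
RFC 4180 with LF line endings; floats are written with round-trip-safe
`repr`, so write → read → write is byte-identical and no numeric value is
perturbed by export. JSON uses insertion-ordered keys and no timestamps.

## Synthetic cohorts

The simulator draws per-sample mixture weights from a flat Dirichlet over
the catalog, then, per mutation, a signature by weight, a channel from
its profile, and a uniform genome position whose pyrimidine-normalized
context matches the channel (positions are pre-indexed by context, so
sampling is rejection-free). Ref/alt are emitted on the genome's literal
strand, so roughly half of planted mutations exercise the
reverse-complement path. Toy genomes are i.i.d. uniform bases on a single
contig; at 10 kb and above they are regenerated (incremented sub-seed)
until all 32 pyrimidine-centred contexts occur, which a uniform draw
satisfies essentially always. Every generator takes one explicit integer
seed and touches no global random state, so identical seeds give
byte-identical MAF/FASTA/TSV output.

What the simulator emulates is exactly the mixture model the refit
assumes — multinomial channel counts from a convex combination of
catalog profiles. It does not emulate GC content or regional mutation-
rate covariates, sequencing error, subclonality, or catalog
misspecification. Passing recovery tests therefore demonstrate
correctness of the pipeline under its own model, not robustness of NNLS
refitting on real tumors.

## Problem sizes and defaults

Default study conditions for end-to-end validation: cohorts of 20
samples with 10,000 mutations each, a 5-signature catalog drawn with
Dirichlet concentration 0.2 (spiky, signature-like profiles), on a
100 kb toy genome; recovery of relative exposures then shows mean L1
error well under 0.05, the bound frozen into the tests. Unit and
property tests use smaller instances (300-mutation cohorts, n ≤ 8
distance matrices) where the property checked does not depend on scale.
The acceptance script runs 5 such cohorts per invocation, enough for
stable means at a few seconds of runtime.

## Known limitations

- SBS96 only: no DBS78/ID83, no extended (192/288/1536) or
  transcriptional-strand contexts.
- Refitting only: no de novo signature extraction (NMF), bootstrap
  intervals, or signature subset selection.
- Single linkage rule (UPGMA) by design; no complete/Ward variants.
- UMAP embedding is delegated to third-party implementations via the
  exported tables; no hook is shipped.
- The MAF reader validates only the six mapped columns, not the full
  GDC column set; VCF input must be converted upstream.
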