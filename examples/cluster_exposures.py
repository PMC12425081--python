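"""Double-cluster a fitted exposure matrix for heatmap ordering.

Simulates and refits a small cohort, clusters samples and signatures
independently by cosine-similarity UPGMA, and prints the clustered
orders, the sample tree in Newick form, and the root annotation. The
similarity on each internal node is the average-linkage value (1 minus
the merge distance) of the two clusters beneath it; node totals sum the
mutations of the samples underneath.
"""

from sigspect import (
    build_spectra,
    double_cluster,
    fit_cohort,
    gen_catalog,
    gen_cohort,
    gen_genome,
    to_newick,
)

genome = gen_genome(50_000, seed=7)
catalog = gen_catalog(4, concentration=0.2, seed=8)
truth = gen_cohort(genome, catalog, n_samples=6,
                   mutations_per_sample=1_000, seed=9)
spectra = build_spectra(truth.maf, genome)
cohort = fit_cohort(spectra, catalog)

result = double_cluster(
    cohort.exposures, cohort.sample_ids, cohort.signature_ids,
    row_totals=dict(zip(cohort.sample_ids, cohort.exposures.sum(axis=1))),
)

print("sample order:   ", " ".join(result.row_order))
print("signature order:", " ".join(result.col_order))
root = result.row_tree
print(f"root: similarity={root.similarity:.4f} "
      f"total_mutations={root.total_mutations:.0f}")
print("sample tree (Newick):")
print(to_newick(root))
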