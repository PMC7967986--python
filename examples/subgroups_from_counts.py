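"""Learn microbial subgroups from an OTU count table.

Generates a small synthetic 16S-style count table, applies the standard
preprocessing chain (total-count normalization, abundance/prevalence
filtering, x1000 integer rescale), fits a latent Dirichlet allocation
model by collapsed Gibbs sampling, and prints what the subgroups are
made of and how they are distributed across samples.
"""

from microlda import (
    LdaHyperparams,
    fit_lda_gibbs,
    filter_otus,
    normalize_total_count,
    rescale_to_counts,
    summarize_subgroups,
    synthetic,
    top_genera,
)

# a corpus drawn from the LDA generative process itself: 120 samples,
# 60 OTUs, 4 planted subgroups with mostly separate OTU vocabularies
table, truth = synthetic.generate_lda_corpus(
    n_samples=120, n_otus=60, K=4, reads_per_sample=1000, seed=7, separation=0.9
)
anc = synthetic.generate_ancillary(
    n_otus=60, genus_pool_size=10, unknown_genus_fraction=0.2,
    arrhythmic_set_sizes={"demo": 8}, seed=7,
)

norm = normalize_total_count(table)
filtered = filter_otus(norm, abundance_threshold=0.001, prevalence_threshold=0.01)
counts = rescale_to_counts(normalize_total_count(filtered), factor=1000)
print(f"{table.n_otus} OTUs -> {counts.n_otus} after the abundance/prevalence filter")

model = fit_lda_gibbs(counts, LdaHyperparams(K=4, n_sweeps=800, n_burnin=400, seed=1))

print("\nTop genera per subgroup (probability of the genus within the subgroup):")
for row in top_genera(model.phi, counts.otu_ids, anc["taxonomy"], n_top=3):
    named = ", ".join(f"{g} {p:.2f}" for g, p in row["top"])
    print(f"  {row['subgroup']}: {named}  (unknown genus: {row['unknown_genus_percent']:.1f}%)")

summary = summarize_subgroups(model.theta)
print(
    f"\nPer-sample maximum subgroup probability: mean "
    f"{summary.max_per_sample.mean():.3f} (a high value means one subgroup"
    " dominates that sample's microbiota)"
)
for t, mean, sd in zip(summary.thresholds, summary.mean_counts, summary.sd_counts):
    print(f"  subgroups with probability > {t:g}: {mean:.1f} +- {sd:.1f} per sample")
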