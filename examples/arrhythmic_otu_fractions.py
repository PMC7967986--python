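"""Subgroup composition with respect to externally defined OTU lists.

Given a fitted subgroup-OTU matrix and named OTU lists (here,
synthetic stand-ins for OTUs that lose circadian rhythmicity in
metabolic disease), sums each subgroup's probability mass over each
list, and clusters the subgroups hierarchically (Ward linkage on the
log-transformed full subgroup-OTU matrix) to show which subgroups are
structurally similar.
"""

from microlda import (
    LdaHyperparams,
    arrhythmic_fraction,
    cluster_subgroups,
    fit_lda_gibbs,
    synthetic,
)

table, truth = synthetic.generate_lda_corpus(
    n_samples=100, n_otus=60, K=5, reads_per_sample=800, seed=13, separation=0.85
)
anc = synthetic.generate_ancillary(
    n_otus=60, genus_pool_size=10, unknown_genus_fraction=0.15,
    arrhythmic_set_sizes={"all_arrhythmic": 18, "obesity_specific": 10,
                          "t2dm_specific": 4},
    seed=13,
)
model = fit_lda_gibbs(table, LdaHyperparams(K=5, n_sweeps=600, n_burnin=300, seed=2))

fractions = arrhythmic_fraction(model.phi, table.otu_ids, anc["otu_sets"])
print("Percentage of each subgroup made of the listed OTUs:")
print(fractions.to_string(float_format=lambda v: f"{v:.1f}"))
print(
    "\nA subgroup with a high percentage is dominated by OTUs from that list;"
    " values are percentages of the subgroup's total OTU probability mass."
)

dendro = cluster_subgroups(model.phi, n_clusters=2)
print("\nSubgroup dendrogram (newick):", dendro["newick"])
print("Two-cluster cut:", dict(zip(dendro["labels"], dendro["clusters"])))
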