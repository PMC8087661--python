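"""Per-participant PCA across the three task contrasts.

Decomposes each 78 x 3 beta matrix, summarizes explained variance by group,
and pools sign-aligned component-2 loadings into a feature table.
"""

from taskpca import (
    SyntheticConfig,
    align_component_signs,
    build_feature_matrix,
    generate_dataset,
    subject_pca,
    summarize_explained_variance,
)

dataset = generate_dataset(SyntheticConfig(seed=42))
pcas = [subject_pca(m) for m in dataset.beta_matrices]

one = pcas[0]
print(f"{one.participant_id}: singular values "
      f"{[round(float(s), 3) for s in one.singular_values]}, explained "
      f"{[round(float(100 * p), 1) for p in one.explained_proportions]} %")

summary = summarize_explained_variance(pcas, dataset.labels,
                                       group_names={1: "PI", 0: "HC"})
print(summary.round(2).to_string(index=False))
# Component 1/2/3 explain about 70/20/10 % of the variance in both groups,
# the regime the generator is configured for.

aligned = align_component_signs(pcas, pc_index=2)
table = build_feature_matrix(aligned, pc_index=2, labels=dataset.labels)
print(f"pooled PC2 loading table: {table.values.shape} (ROIs x participants)")
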