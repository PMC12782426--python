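"""Detect cell-cell heterogeneity in migratory rules.

Fits a distinct response function to every cell of a planted
two-subpopulation dataset, ranks cells by how well the population-level
model predicts them, and summarizes the structure with the pairwise
similarity matrix and a PCA of the per-cell kernels.
"""

import numpy as np

from erkmech import (
    LagSpec,
    RidgeConfig,
    build_design,
    generate_two_population_dataset,
    pca_response_functions,
    per_cell_analysis,
    ridge_fit,
    similarity_matrix,
    subgroup_mean_rf,
)

L = 12
table, labels = generate_two_population_dataset(
    n_cells_per_group=25, n_frames=300, L=L, noise_fraction=0.1, seed=3, flip="full"
)

# population-level fit (dominated by whichever rule fits the pooled data)
X, y, _ = build_design(table, LagSpec(L=L))
pop = ridge_fit(X, y, RidgeConfig(lambda_=1.0), lag_spec=LagSpec(L=L))

rf_set = per_cell_analysis(table, pop, lambda_=1.0)
sim, ids = similarity_matrix(rf_set)
groups = np.array([labels[c] for c in ids])
same = groups[:, None] == groups[None, :]
off = ~np.eye(len(ids), dtype=bool)
within = sim[same & off].mean()
between = sim[~same].mean()
print(f"cells analyzed: {len(ids)}")
print(f"mean within-group similarity:  {within:+.3f}")
print(f"mean between-group similarity: {between:+.3f}")
print(f"block contrast (within - between): {within - between:.3f}")

scores, evr = pca_response_functions(rf_set)
print(f"PCA of per-cell response functions: PC1 explains {100 * evr[0]:.1f}%, "
      f"PC2 {100 * evr[1]:.1f}% of variance")

best, worst = subgroup_mean_rf(rf_set, n_best=10, n_worst=10)
print(f"best-predicted 10-cell mean ERK kernel peak:  {best.kernel('erk_grad')[0]:+.3f}")
print(f"worst-predicted 10-cell mean ERK kernel peak: {worst.kernel('erk_grad')[0]:+.3f}")
print("(a large block contrast and a dominant PC1 reveal the planted "
      "subpopulations; the worst-predicted subgroup follows the inverted "
      "rule, so its mean ERK kernel has the opposite sign.)")
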