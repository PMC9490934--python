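"""Build the weighted co-expression network and detect modules.

Pearson correlations are soft-thresholded (|r|^beta with beta picked by
the scale-free topology criterion), transformed into topological
overlap, clustered with average linkage and cut with the hybrid tree
cut. The detected partition is compared against the planted one.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from lncnet import network, synthetic

ds = synthetic.generate_dataset(synthetic.SyntheticConfig(seed=1))

cor = network.correlation_matrix(ds.expression)
beta, fits = network.pick_soft_threshold(cor)
print(f"chosen soft threshold beta = {beta} "
      f"(signed R^2 = {fits.loc[beta, 'signed_r2']:.3f}, "
      f"mean connectivity = {fits.loc[beta, 'mean_connectivity']:.1f})")

adj = network.soft_adjacency(cor, beta)
tom = network.topological_overlap(adj)
dissim = 1 - tom
np.fill_diagonal(dissim.values, 0.0)
dend = network.average_linkage(dissim)
modules = network.hybrid_tree_cut(dend, dissim)

print(f"detected modules: {modules.sizes()}")
mask = modules.labels != network.UNASSIGNED
ari = adjusted_rand_score(ds.truth.module_of[mask], modules.labels[mask])
print(f"adjusted Rand index vs planted modules (unassigned excluded): "
      f"{ari:.3f}")
print("ARI = 1 would be a perfect match; values above 0.9 mean the planted "
      "co-expression structure was recovered nearly gene-for-gene.")
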