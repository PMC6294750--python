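"""Segment a mixed tract population into bundles by shape.

Pairwise mean-closest-point distances feed a Gaussian affinity; the
normalized affinity's eigenvectors embed each tract as a 2-D point; k-means
cuts the embedding. On the purse-string truth tracts the two mirrored
bundles separate perfectly.
"""

import numpy as np

from myotract.cluster import (
    cluster_purity, cluster_tracts, distance_matrix, spectral_embed,
)
from myotract.phantom import PhantomSpec, make_geometry

truth = make_geometry(PhantomSpec(geometry_kind="purse_string", seed=7))
tracts = truth.tracts
true_labels = np.array([t.bundle_label for t in tracts])

D = distance_matrix(tracts)
print(f"{len(tracts)} tracts; pairwise distance "
      f"median {np.median(D[np.triu_indices_from(D, 1)]):.1f} mm")

emb = spectral_embed(tracts)
labels = cluster_tracts(emb, k=2, seed=0)
purity = cluster_purity(labels, true_labels)
print(f"embedding eigenvalues: {np.round(emb.eigenvalues, 4)}")
print(f"cluster sizes: {np.bincount(labels).tolist()}, "
      f"purity vs truth: {purity:.3f}")

# Purity 1.0 means every tract landed in the cluster dominated by its own
# bundle: the shape distance separates the concave-up from the concave-down
# arc family even though the two overlap in space at the midline.
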