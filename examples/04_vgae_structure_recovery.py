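"""Fit a VGAE to a toy community graph and inspect edge reconstruction.

Two 6-cliques joined by a single bridge, identity node features.  After
training, the inner-product decoder should assign clearly higher
probability to within-clique pairs than to cross-clique non-edges — the
latent space has learned the community structure from connectivity alone.
"""

import numpy as np

from graphmil.vgae import fit_vgae

A = np.zeros((12, 12))
A[:6, :6] = 1.0
A[6:, 6:] = 1.0
A[0, 6] = A[6, 0] = 1.0  # one bridging edge
np.fill_diagonal(A, 1.0)

_, A_hat = fit_vgae(A, latent_dim=8, hidden=16, epochs=200, seed=0)

within, cross = [], []
for i in range(12):
    for j in range(i + 1, 12):
        if (i < 6) == (j < 6):
            within.append(A_hat[i, j])
        elif not (i == 0 and j == 6):
            cross.append(A_hat[i, j])

print(f"mean reconstructed probability, within-clique edges: "
      f"{np.mean(within):.3f}")
print(f"mean reconstructed probability, cross-clique non-edges: "
      f"{np.mean(cross):.3f}")

# the KL prior compresses probabilities toward 0.5 on a graph this small,
# so also look at the ordering, which is what link prediction uses
from sklearn.metrics import roc_auc_score

auc = roc_auc_score([1] * len(within) + [0] * len(cross), within + cross)
print(f"ranking AUC (within-clique pairs vs cross non-edges): {auc:.3f} — "
      "1.0 means every community pair outranks every cross pair")
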