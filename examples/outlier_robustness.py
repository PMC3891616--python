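"""Compare center recovery of FCM and the hybrid under gross outliers.

Draws two Gaussian blobs at (+-3, 0), contaminates them with 5%
uniform outliers from a box an order of magnitude wider than the
clusters, and measures how far each algorithm's prototypes move from
the true centers.
"""

import numpy as np

from pfclust import HyperParams, make_blobs, run_fcm, run_hpfcm


def worst_error(V, truth):
    V = V[np.argsort(V[:, 0])]
    return float(np.max(np.abs(V - truth)))


print(f"{'seed':>4} {'FCM err':>9} {'hybrid err':>11}")
for seed in range(5):
    ds = make_blobs(K=2, n_per_cluster=100, centers=((-3, 0), (3, 0)),
                    spread=0.5, n_outliers=10, seed=seed)
    fcm = run_fcm(ds.X, 2, HyperParams(seed=seed))
    hyb = run_hpfcm(ds.X, 2, HyperParams(seed=seed))
    print(f"{seed:>4} {worst_error(fcm.V, ds.true_centers):>9.3f}"
          f" {worst_error(hyb.V, ds.true_centers):>11.3f}")

print(
    "\nWorst-coordinate distance of the estimated centers from (+-3, 0)."
    " The fuzzy run must give every outlier membership ~1/2 in each"
    " cluster, so the prototypes drift; the hybrid's possibilistic stage"
    " assigns them near-zero typicality in both clusters and stays close"
    " to the true centers."
)
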