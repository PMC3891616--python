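"""Segment a noisy synthetic tissue phantom and score the result.

Builds a nested-disc phantom (background / CSF / GM / WM analog) with
7% Gaussian noise, clusters the pixel intensities with the hybrid
algorithm, and reports per-tissue sensitivity, specificity and
classification accuracy against the known label map.
"""

import numpy as np

from pfclust import (
    HyperParams,
    evaluate_labels,
    features_to_labelmap,
    image_to_features,
    make_phantom,
    run_hpfcm,
)

image, truth = make_phantom((64, 64), tissue_means=(0.05, 0.35, 0.65, 0.95),
                            noise_pct=7, seed=7)
X = image_to_features(image)

res = run_hpfcm(X, 4, HyperParams(seed=0), n_init=3)
segmentation = features_to_labelmap(res.labels, image.shape)

report = evaluate_labels(segmentation.ravel(), truth.ravel())
print(f"overall clustering accuracy (Huang h): {report.huang_h:.3f}")
print(f"{'tissue':>7} {'Se':>7} {'Sp':>7} {'CA':>7}")
for cls in sorted(report.per_class):
    s = report.per_class[cls]
    print(f"{cls:>7} {s['se']:>7.3f} {s['sp']:>7.3f} {s['ca']:>7.3f}")

print(
    "\nSe: fraction of each true tissue recovered; Sp: fraction of"
    " non-tissue kept out; CA: overall per-tissue accuracy. At 7% noise"
    " the intensity histograms of adjacent tissues overlap slightly, so"
    " values just below 1 come from pixels near the class boundaries."
)
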