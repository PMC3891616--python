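"""Score a clustering against ground truth with label matching.

Cluster numbering is arbitrary, so evaluation first matches clusters to
classes by optimal assignment on the contingency table, then counts
agreements (Huang accuracy) and per-class confusion statistics.
"""

import numpy as np

from pfclust import confusion, evaluate_labels, huang_accuracy, se_sp_ca

true = np.array([0] * 6 + [1] * 6 + [2] * 6)
# a clustering that found the right groups under permuted labels,
# with two objects misplaced
pred = np.array([2] * 6 + [0] * 5 + [1] + [1] * 5 + [0])

rep = evaluate_labels(pred, true)
print("cluster -> class matching:", rep.matching)
print(f"Huang accuracy h = {rep.huang_h:.3f}   (16 of 18 agree after matching)")

mask_pred = pred == 2          # cluster matched to class 0
mask_true = true == 0
c = confusion(mask_pred, mask_true)
se, sp, ca = se_sp_ca(c)
print(f"class 0 one-vs-rest: TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}"
      f" -> Se={se:.3f} Sp={sp:.3f} CA={ca:.3f}")

assert huang_accuracy(pred, true) == rep.huang_h
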