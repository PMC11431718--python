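"""Sensitivity / specificity / accuracy arithmetic for gene classification.

Reproduces the metric layout of a two-method comparison: an initial analysis
over all genes, then two conditional methods evaluated on the genes that were
initially significant (their denominators are the selected genes only).
"""

import numpy as np

from taucor import performance


def pvec(n_called: int, n_total: int) -> np.ndarray:
    p = np.full(n_total, 0.5)
    p[:n_called] = 1e-8
    return p


rows = [
    ("initial GBA", (15, 28), (54, 423)),
    ("method A + GBA", (10, 15), (15, 54)),
    ("method B + GBA", (12, 15), (5, 54)),
]

print(f"{'analysis':16s} {'called+':>8s} {'called-':>8s} "
      f"{'sens':>6s} {'spec':>6s} {'acc':>6s}")
for label, pos, neg in rows:
    perf = performance(pvec(*pos), pvec(*neg), threshold=2.5e-6)
    r = perf.rounded()
    print(f"{label:16s} {pos[0]:>4d}/{pos[1]:<3d} {neg[0]:>4d}/{neg[1]:<3d} "
          f"{r['sensitivity']:>6.2f} {r['specificity']:>6.2f} {r['accuracy']:>6.2f}")
# 'called+' = truly associated genes called / total; 'called-' = non-associated
# genes called / total.  Accuracy is the prevalence-weighted combination of
# sensitivity and specificity.
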