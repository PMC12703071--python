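"""The evaluation metrics on a hand-made prediction set.

Shows top-1/top-3 accuracy, macro and weighted F1, the positional metrics
PMF/PSE (computed only over samples where both label and prediction are
nonzero), and the binary collapse (class 0 vs any site).
"""

import numpy as np

from dicersite import PredictionSet, evaluate

rng = np.random.default_rng(1)
n_classes = 14

# labels: one third negatives (class 0), the rest uniform site intervals
labels = rng.choice(np.arange(n_classes), size=60, p=[1 / 3] + [2 / (3 * 13)] * 13)
# predictions: correct 70% of the time, otherwise shifted by one interval
preds = labels.copy()
wrong = rng.random(60) > 0.7
preds[wrong] = np.clip(labels[wrong] + rng.choice([-1, 1], wrong.sum()), 0,
                       n_classes - 1)
probs = np.full((60, n_classes), 0.01)
probs[np.arange(60), preds] = 1.0
probs /= probs.sum(axis=1, keepdims=True)

report = evaluate(PredictionSet.from_probs(labels, probs))
print(f"top1={report.top1:.3f}  top3={report.top3:.3f}")
print(f"macro F1={report.macro_f1:.3f}  weighted F1={report.weighted_f1:.3f}")
print(f"PMF={report.pmf:.3f}  PSE={report.pse:.3f}")
b = report.binary
print(f"binary: acc={b['acc']:.3f} spe={b['spe']:.3f} "
      f"sen={b['sen']:.3f} mcc={b['mcc']:.3f}")
# PSE near 0.3 reflects that errors here are one-interval shifts; PMF is
# the fraction of site-bearing calls placed exactly right.
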