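"""Evaluate simulated classifier predictions and compare two models.

Shows the full metric surface: confusion matrix, one-vs-rest per-class
rates, macro/micro overall rows, ROC-AUC, and McNemar's paired test between
two prediction sets on the same samples.
"""

import numpy as np

from dermofusion.metrics import (PairedPredictions, class_metrics,
                                 confusion_matrix, macro_overall,
                                 mcnemar_test, micro_accuracy, roc_auc_ovr)

rng = np.random.default_rng(1)
n, k = 400, 7
y = rng.integers(0, k, n)

def simulate(accuracy):
    pred = y.copy()
    flip = rng.random(n) > accuracy
    pred[flip] = rng.integers(0, k, flip.sum())
    return pred

pred_a = simulate(0.90)   # stronger model
pred_b = simulate(0.70)   # weaker model

cm = confusion_matrix(y, pred_a, k)
per_class = class_metrics(cm)
print("per-class sensitivity (%):",
      np.round(per_class["sensitivity"].to_numpy(), 1))
print(f"macro sensitivity: {macro_overall(per_class['sensitivity'])}%, "
      f"micro accuracy: {micro_accuracy(cm):.2f}%")

scores = np.eye(k)[pred_a] * 0.8 + rng.random((n, k)) * 0.2
aucs = roc_auc_ovr(y, scores)
print("one-vs-rest AUC per class:", np.round(aucs, 3))

paired = PairedPredictions.from_correctness(pred_a == y, pred_b == y)
statistic, p = mcnemar_test(paired)
print(f"McNemar discordants b={paired.b} c={paired.c}; statistic="
      f"{statistic:.2f}, p={p:.2e}")
print("-> small p: the two models' error patterns differ significantly.")
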