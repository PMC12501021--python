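"""Run the full hybrid forward pass on one synthetic image.

The image feeds two branches (patch-token transformer with SDEB, and the
pruned DenseNet); their projected features are summed and classified into
seven lesion classes.
"""

import numpy as np

from dermofusion.hybrid_model import HybridModel, tiny_config
from dermofusion.synth import CLASS_NAMES, generate_dataset

model = HybridModel(tiny_config(seed=0))
model.eval()

images, labels, _ = generate_dataset([0, 0, 0, 0, 1, 0, 0], (32, 32), seed=3)
probs = model.predict_proba(images[0])

print("class probabilities (untrained weights):")
for name, p in zip(CLASS_NAMES, probs):
    print(f"  {name:5s} {p:.4f}")
print(f"sum = {probs.sum():.6f} (softmax output lies on the simplex)")
print(f"argmax = {CLASS_NAMES[int(np.argmax(probs))]} -- before training the "
      "distribution reflects random weights, not the lesion")
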