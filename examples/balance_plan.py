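"""Build a class-balancing augmentation plan and materialise a toy class.

The plan mirrors the HAM10000-style training inventory: each minority class
gets an integer factor F_c ~ round(8000 / N_c) so every class lands near
8000 images; the dominant nevus class is left untouched.
"""

import numpy as np

from dermofusion.balance import (ImageRecord, build_plan,
                                 materialize_balanced_dataset)

inventory = {"DF": 153, "VASC": 162, "AKIEC": 555, "SCC": 402,
             "BKL": 1679, "MEL": 2894, "NV": 8240}
plan = build_plan(inventory, target=8000, overrides={"VASC": 52})
print(plan.to_string(index=False))
print(f"balanced range: {plan['target'].min()} .. {plan['target'].max()} "
      "images per class")

# materialise a small class at factor 4: 3 originals + 9 augmented variants
rng = np.random.default_rng(0)
records = [ImageRecord(f"img_{i}", "toy", rng.uniform(0, 255, (16, 16, 3)))
           for i in range(3)]
toy_plan = build_plan({"toy": 3}, target=12)
out = materialize_balanced_dataset(records, toy_plan, seed=5)
n_aug = sum(r.parent_id is not None for r in out)
print(f"toy class: {len(out)} images total ({n_aug} augmented), every "
      "augmented image traces to a parent id")
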