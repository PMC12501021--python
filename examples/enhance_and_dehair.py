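"""Enhance a synthetic dermoscopy image and remove its drawn hairs.

Builds a lesion image with three dark hair strokes, runs the two-stage
enhancement (adaptive average filter + Laplacian sharpening) and the
morphological hair-removal step, then reports how well the detected mask
covers the known stroke pixels.
"""

import numpy as np

from dermofusion.preprocess import (EnhancementConfig, HairRemovalConfig,
                                    detect_hair_mask, enhance_image,
                                    estimate_noise_variance, inpaint_hair)
from dermofusion.synth import HairSpec, LesionSpec, draw_hairs, generate_lesion_image

img, _ = generate_lesion_image(LesionSpec(class_id=4, noise_sigma=3.0),
                               (96, 96), seed=11)
hairy, truth = draw_hairs(img, HairSpec(n_strokes=3, thickness=2), seed=12)

sigma2 = estimate_noise_variance(hairy, window=7)
enhanced = enhance_image(hairy, EnhancementConfig(window=7))
mask = detect_hair_mask(enhanced, HairRemovalConfig())
clean = inpaint_hair(enhanced, mask, HairRemovalConfig())

recall = (mask.astype(bool) & truth).sum() / truth.sum()
changed = np.any(clean != enhanced, axis=-1).sum()

print(f"estimated noise variance: {sigma2:.2f} intensity^2")
print(f"hair pixels drawn: {truth.sum()}, mask recall: {recall:.3f}")
print(f"pixels repainted by inpainting: {changed}")
print("-> recall near 1.0 means the line-closing detector found nearly all")
print("   stroke pixels; only masked pixels were repainted.")
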