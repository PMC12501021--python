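"""Patch arithmetic and positional encoding for the transformer branch.

A 600 x 450 image tiles into 300 non-overlapping 30 x 30 patches; each
patch becomes one token, and a fixed sinusoidal table (frequency base 1000)
encodes its position.
"""

import numpy as np

from dermofusion.patch_embed import num_patches, patchify, sinusoidal_pe, unpatchify

h, w, p = 450, 600, 30
n = num_patches(h, w, p)
print(f"{w} x {h} image, {p} x {p} patches -> N = {n} tokens")

img = np.random.default_rng(0).uniform(0, 255, (h, w, 3))
tiles, grid = patchify(img, p)
exact = np.array_equal(unpatchify(tiles, grid, p), img)
print(f"patch grid {grid[0]} x {grid[1]}, tiling round trip exact: {exact}")

d = 256
pe = sinusoidal_pe(n, d)
print(f"positional table {pe.shape}; row 0 = (sin 0, cos 0, ...) = "
      f"({pe[0, 0]:.0f}, {pe[0, 1]:.0f}, ...)")
print(f"row 1 starts sin(1)={pe[1, 0]:.6f}, cos(1)={pe[1, 1]:.6f}")
print(f"flattened encoder output per image: {n} x {d} = {n * d} features")
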