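"""The Arnold cat map is periodic: iterate it enough times and every image
returns to its original state.

Computes the period for a range of grid sizes and demonstrates the exact
restoration on a random image.
"""

import numpy as np

from scramblenet import ArnoldParams, arnold_period, encrypt

params = ArnoldParams()  # the classical cat map matrix [[1,1],[1,2]]

print("side  period")
for n in (2, 8, 16, 32, 64, 128, 224):
    print(f"{n:4d}  {arnold_period(params, n):6d}")

n = 64
period = arnold_period(params, n)
img = np.random.default_rng(0).integers(0, 256, size=(n, n), dtype=np.uint8)
restored = encrypt(img, "arnold", ArnoldParams(iterations=period))
print(f"\n{period} iterations on a {n}x{n} image restore it bit-exactly:",
      np.array_equal(restored, img))
# The period depends on the grid size in an irregular, number-theoretic way
# (e.g. 3 for side 2, 48 for side 64); it equals the multiplicative order
# of the cipher matrix modulo the side length.
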