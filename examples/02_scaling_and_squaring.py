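"""Amplifying a small displacement field by scaling and squaring.

A spatially constant displacement of 0.001 voxels grows by exactly
2^h after h squaring layers (here 256x for h = 8).  With smoothing
enabled and a random smooth input, the same machinery produces a large
but fold-free deformation: every Jacobian determinant stays positive.
"""

import numpy as np

from topowarp import (
    DisplacementField,
    Grid2D,
    SmoothingSpec,
    displacement_activation,
    jacobian_determinants,
    scaling_and_squaring,
)

grid = Grid2D(16, 16)
u = DisplacementField(np.stack([np.full((16, 16), 1e-3), np.zeros((16, 16))]), grid)
phi = scaling_and_squaring(u, h=8, smoothing=SmoothingSpec(sigma=0.0, k=1))
ratio = phi.displacement.values[0, 8, 8] / 1e-3
print(f"constant 0.001-voxel field, h=8 -> interior displacement x{ratio:.0f} (= 2^8)")

rng = np.random.default_rng(0)
grid = Grid2D(32, 32)
from scipy.ndimage import gaussian_filter

raw = gaussian_filter(rng.normal(0, 1, (2, 32, 32)), (0, 2, 2))
raw *= 0.1 / np.abs(raw).max()
u1 = displacement_activation(raw)  # each component now < 0.5 voxels
for sigma in (2.0, 0.0):
    phi = scaling_and_squaring(u1, h=8, smoothing=SmoothingSpec(sigma, 3))
    rep = jacobian_determinants(phi)
    print(
        f"random smooth field, sigma={sigma}: max |u| = "
        f"{np.abs(phi.displacement.values).max():.2f} voxels, "
        f"{rep.percent_nonpositive:.2f}% non-positive Jacobian determinants"
    )
print("Gaussian smoothing between compositions is what keeps the")
print("amplified field free of folding voxels.")
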