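"""Discrete vs continuous field composition, in one dimension.

Composing a piecewise-linear 1D deformation with itself on a discrete
grid evaluates the interpolated field at its own grid outputs.  The
classic worked example: Phi = (0, 1.5, 2.5, 3) on x = (0, 1, 2, 3),
so Phi^2(1) = Phi(Phi(1)) = Phi(1.5) = 2 under linear interpolation.
Storing only grid values loses information between points, which is why
the 2D machinery adds smoothing and finer grids.
"""

import numpy as np

from topowarp import compose_1d

phi1 = np.array([0.0, 1.5, 2.5, 3.0])
phi2 = compose_1d(phi1)
phi4 = compose_1d(phi1, n=2)

print("x        :", np.arange(4))
print("Phi^1(x) :", phi1)
print("Phi^2(x) :", phi2)
print("Phi^4(x) :", phi4)
print()
print(f"Phi^2(1) = Phi^1(Phi^1(1)) = Phi^1(1.5) = {phi2[1]:.1f}")
print("Each composition doubles the effective displacement; repeated")
print("composition is how small fields are amplified into large ones.")
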