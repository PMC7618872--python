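"""Generating synthetic phantoms with known topology.

Labels are manufactured by warping a prior with a random fold-free
deformation, so every label provably carries the declared Betti
numbers; images add piecewise-constant intensities, noise, Fourier
line dropout and geometric augmentation.
"""

import numpy as np

from topowarp import PhantomSpec, betti_2d, dice_score, make_dataset

spec = PhantomSpec.for_task("myo", H=64, W=64, n_samples=12, seed=0)
ds = make_dataset(spec)

print(ds.manifest[["sample_id", "family_id", "split", "b0_ch0", "b1_ch0"]]
      .to_string(index=False))
d = [dice_score(s.prior[0], s.label[0]) for s in ds.samples]
print(f"\nDice(prior, label): mean {np.mean(d):.2f} (min {np.min(d):.2f})")
print("Labels are clearly deformed away from the prior (Dice < 0.95) yet")
print("every one keeps the annulus topology (b0=1, b1=1) by construction.")

scene = PhantomSpec.for_task("cardiac_scene", H=64, W=64, n_samples=3, seed=1)
ds3 = make_dataset(scene)
s = ds3.samples[0]
print("\ncardiac phantom channels:",
      [tuple(betti_2d(ch)) for ch in s.label],
      "union:", tuple(betti_2d(np.any(s.label, axis=0))))
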