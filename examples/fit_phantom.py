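"""Round-trip a digital phantom: synthesize, correct, fit, aggregate.

Generates a 16x16x8 phantom (CSF slab at R2t* = 1 s^-1, labeled
gray-matter regions near 17 s^-1) with a 1 Hz/mm through-slab gradient,
navigator phase drift and SNR-100 Rician noise, then runs the estimation
chain and compares fitted class medians with the ground truth.
"""

import numpy as np

from r2tstar import FitOptions, estimate_field, fit_volume, navigator_correct
from r2tstar.synthetic import PhantomSpec, make_phantom

spec = PhantomSpec(
    seed=7, snr=100.0, b0_gradient_hz_per_mm=(0, 0, 1.0), nav_amplitude_rad=0.3
)
out = make_phantom(spec)

image = navigator_correct(out.image, out.navigator)   # remove phase drift
field = estimate_field(image)                         # B0 + through-slab gradient
qmaps = fit_volume(image, field, FitOptions(noise_sigma=out.noise_sigma))

labels = out.labels.labels
for name, sel, truth in [
    ("CSF", labels == 1, 1.0),
    ("gray matter", labels >= 100, 17.0),
]:
    fitted = np.median(qmaps.r2t_star_map[sel & qmaps.quality_mask])
    print(f"{name:12s} median R2t* = {fitted:6.2f} s^-1   (truth {truth:.1f})")

print(f"\nestimated through-slab gradient (interior): "
      f"{field.g_through[8, 8, 4]:.3f} Hz/mm (truth 1.0)")
print(f"voxels fit: {int(out.image.brain_mask.sum())}, "
      f"quality-passing: {int(qmaps.quality_mask.sum())}")
print("\nMedians are used because a few mislabeled or artifact voxels")
print("should not drag the regional estimate.")
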