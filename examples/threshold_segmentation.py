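"""Fractional-SUVmax contouring: nested GTVs at 20-50% of intraprostatic SUVmax.

On a noiseless, blur-free phantom the contour carved at each fraction can be
compared with the analytically known iso-fraction truth set: the Dice
coefficient is exactly 1.0 at every fraction, and the volumes shrink as the
threshold rises.
"""

from petseg import (
    PhantomSpec,
    analytic_fraction_mask,
    dice,
    generate_phantom,
    intraprostatic_suvmax,
    threshold_segment,
)

ds = generate_phantom(PhantomSpec(blur_fwhm_mm=0.0, noise_sd_suv=0.0, seed=3))
suvmax = intraprostatic_suvmax(ds.suv, ds.prostate)
print(f"intraprostatic SUVmax = {suvmax:.1f}")
print(f"{'fraction':>8} {'SUV thr':>8} {'volume ml':>10} {'DSC vs analytic truth':>22}")
for fraction in (0.2, 0.3, 0.4, 0.5):
    res = threshold_segment(ds.suv, ds.prostate, fraction)
    d = dice(res.gtv, analytic_fraction_mask(ds, fraction))
    print(f"{fraction:8.0%} {res.suv_threshold:8.2f} {res.gtv.volume_ml:10.2f} {d:22.3f}")

# Volumes fall monotonically with the fraction (higher threshold -> smaller,
# more specific contour); DSC = 1.0 confirms the image thresholding and the
# geometric construction agree voxel for voxel.
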