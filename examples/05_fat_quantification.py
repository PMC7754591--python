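"""Quantify intramuscular fat on the Dixon fat-fraction image.

The fat-fraction image is built per voxel as fat/(fat+water)*1000‰, the
T1-derived masks are transferred onto it by rigid mutual-information
registration, and mean and absolute fat content are reported inside the
analysis VOI.
"""

import numpy as np

from handmuscle import (
    PhantomSpec,
    VoiSpec,
    compute_fat_fraction,
    make_dixon_phantom,
    make_t1_phantom,
    quantify,
    register_rigid,
    transfer_mask,
)

spec = PhantomSpec(seed=3)
t1, csa_truth, muscle_truth = make_t1_phantom(spec)
fat, water, ff_truth = make_dixon_phantom(spec, muscle_truth)

ff = compute_fat_fraction(fat, water)
transform = register_rigid(ff, t1, seed=1)  # here T1 and FF share a frame
print(f"registration offset (mm): {np.round(transform.translation_mm, 3)} "
      f"(near zero: the phantom pair is already aligned)")

muscle_ff = transfer_mask(muscle_truth, transform, ff)
hand_ff = transfer_mask(csa_truth, transform, ff)
voi = VoiSpec(2, 13)  # the metacarpal region picked by the operator
report = quantify(ff, muscle_ff, hand_ff, voi, transform=transform)

truth = float(ff_truth.data[np.asarray(muscle_truth.data)][:].mean())
print(f"muscle volume: {report.muscle_volume_mm3:9.1f} mm^3")
print(f"mean fat fraction: {report.mean_fat_fraction_permille:6.1f} permille "
      f"({report.mean_fat_fraction_percent:.1f}%)")
print(f"absolute fat: {report.absolute_fat_mm3:9.1f} mm^3 (fat-equivalent volume)")
print(f"ground-truth mean over all muscle: {truth:.1f} permille")
print("-> the report recovers the constructed fat map; on patient data the")
print("   registration bridges the T1 and Dixon acquisitions.")
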