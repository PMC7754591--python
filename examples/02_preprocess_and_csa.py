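"""Bias-field correction, hand CSA extraction and grey-value normalization.

A 30% multiplicative bias field is applied to the phantom, removed again
by the polynomial correction, and the cortical-bone/muscle histogram
peaks are located so intensities can be mapped to the 0/100 scale used by
all downstream features.
"""

import numpy as np

from handmuscle import (
    PhantomSpec,
    correct_bias_field,
    dice,
    find_histogram_peaks,
    make_t1_phantom,
    normalize_intensities,
    segment_hand_csa,
)

spec = PhantomSpec(seed=1, bias_amplitude=1.3)
t1, csa_truth, muscle_truth = make_t1_phantom(spec)

corrected = correct_bias_field(t1, method="polyfit")
cv_before = t1.data[csa_truth.data].std() / t1.data[csa_truth.data].mean()
cv_after = corrected.data[csa_truth.data].std() / corrected.data[csa_truth.data].mean()
print(f"in-hand coefficient of variation: {cv_before:.4f} -> {cv_after:.4f}")
print("-> the smooth multiplicative inhomogeneity is mostly gone.")

hand = segment_hand_csa(corrected, threshold=70.0)
print(f"hand CSA Dice vs construction truth: {dice(hand, csa_truth):.4f}")

peaks = find_histogram_peaks(corrected, hand)
print(f"histogram peaks: cortical bone {peaks.v_cort:.1f}, muscle {peaks.v_muscle:.1f}")
norm = normalize_intensities(corrected, peaks)
print(f"median normalized muscle intensity: "
      f"{np.median(norm.data[muscle_truth.data]):.1f}")
print("-> the muscle peak maps to 100 by construction; residual bias after")
print("   correction shifts the detected peak (and hence this median) a few")
print("   percent, which is what the normalization absorbs across scans.")
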