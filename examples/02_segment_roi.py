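"""Least-max-value segmentation of the cardiac region of interest.

Builds a clean phantom, derives the gray-histogram threshold, and compares
the recovered RoI cluster with the generator's ground-truth ellipse.
"""

import numpy as np

from cardiofuse import PhantomSpec, generate_phantom_mri, gray_histogram, least_max_value, segment

img, truth = generate_phantom_mri(PhantomSpec(seed=3, impulse_rate=0.0))
lmv = least_max_value(gray_histogram(img))
result = segment(img)

inter = np.count_nonzero(result.labels & truth)
union = np.count_nonzero(result.labels | truth)
print(f"least max value (threshold) : {lmv}")
print(f"RoI pixels (cluster C1)     : {result.roi_pixel_count}")
print(f"true ellipse pixels         : {np.count_nonzero(truth)}")
print(f"Jaccard overlap with truth  : {inter / union:.3f}")
print("Pixels darker than the threshold form the RoI; the overlap near 1")
print("means the dark ellipse was recovered almost exactly.")
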