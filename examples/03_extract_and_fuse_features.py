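"""From one phantom and one ECG beat to a fused six-feature sample.

The four deformation descriptors (area, boundary curvature, intensity mass,
Laplacian roughness) come from the segmented image; heart rate and the linear
blood-pressure surrogate come from the beat waveform.
"""

from cardiofuse import (
    FEATURE_NAMES,
    PhantomSpec,
    extract_ecg_features,
    extract_mri_features,
    fuse_features,
    generate_ecg_beats,
    generate_phantom_mri,
    preprocess_image,
    segment,
)

img, _ = generate_phantom_mri(PhantomSpec(seed=5))
denoised = preprocess_image(img)
seg = segment(denoised)
mri = extract_mri_features(denoised, seg)

beats, _ = generate_ecg_beats(0, n=1, seed=5)  # one normal-class beat
ecg = extract_ecg_features(beats[0])

sample = fuse_features(mri, ecg, label=0, sample_id="demo")
for name, value in zip(FEATURE_NAMES, sample.values):
    print(f"{name:>4s} = {value:10.5f}")
print("nad/nvd are area and intensity fractions of the image; acad/acvd are")
print("shape roughness measures; bp is the documented linear surrogate")
print("(80 + 30*amplitude + 0.2*hr), hr is beats per minute from peak spacing.")
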