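"""Generate a labeled synthetic oral-image dataset.

Renders 4:3 frames of textured pink mucosa, each with at most one lesion
drawn per its class signature (ulcer: yellow core + red halo; low-risk
OPMD: uniform pale patch; high-risk OPMD: pale patch with red blotches;
cancer: dark nodular mass), places lesions by the centered capture rule,
groups normal images onto multi-image patients, and assigns a
patient-disjoint train/test split.
"""

import oralscope as osc

data = osc.generate_dataset([20, 10, 10, 6, 4], height=192, width=256, rng_seed=1)
data = osc.split_by_patient(data, test_fraction=0.3, rng_seed=1)

print("class counts:", data.class_counts)
print("patients:", len(data.patient_ids))
test = data.subset("test")
print("test images:", len(test), "test patients:", len(test.patient_ids))

sample = next(s for s in data.samples if s.label == "cancer")
print(
    f"example cancer image: {sample.pixels.shape} pixels, lesion of "
    f"{sample.lesion_diameter:.0f} px at {sample.lesion_center}"
)
# class counts match the request; no patient appears on both sides of the
# split; lesion centers always fall inside the central ninth of the frame
# (rows [64, 128), cols [85, 170) for a 192 x 256 canvas).
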