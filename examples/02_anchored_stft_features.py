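"""Anchored-STFT featurization of one signal of interest.

Cuts the 3-5.5 s SOI from a synthetic trial (625 samples at 250 Hz) and
runs the reference anchored-STFT configuration: five anchors 16..256
samples at stride 8, 257 one-sided frequency points, mu and beta bands
stacked over three channels.  Prints every framing quantity alongside the
shapes the transform actually produces.
"""

import numpy as np

import anchoreeg as ae

trials = ae.simulate_dataset(ae.SynthConfig(), n_per_class=1, seed=0)
soi = ae.extract_soi(trials[0], ae.SOIWindow(3.0, 5.5))
print(f"SOI: {soi.n_samples} samples from a 2.5 s window at {soi.fs:.0f} Hz")

aset = ae.AnchorSet()  # anchors (16, 32, 64, 128, 256), stride 8
print(f"max admissible anchors K = {ae.max_num_anchors(soi.n_samples)}")
print(f"anchor locations per SOI = {ae.num_anchor_positions(soi.n_samples, aset.stride)}")
for L in aset.lengths:
    pad = ae.zero_padding_length(aset.stride, 78, soi.n_samples, L)
    spec = ae.compute_spectrogram(soi.data[0], soi.fs, L, aset, "C3")
    print(
        f"anchor {L:3d}: overlap {ae.anchor_overlap(L, aset.stride):3d}, "
        f"zero-padding {pad:3d}, spectrogram {spec.values.shape}"
    )

spec16 = ae.compute_spectrogram(soi.data[0], soi.fs, 16, aset, "C3")
print(f"mu slice  (4-15 Hz): {ae.band_slice(spec16, ae.MU_BAND).shape}")
print(f"beta slice (19-30 Hz): {ae.band_slice(spec16, ae.BETA_BAND).shape}")

features = ae.featurize_soi(soi, aset)
shape = features.images[0].shape
print(
    f"feature images: {features.n_anchors} per SOI, each {shape[0]} x {shape[1]} "
    "(22 rows x 2 bands x 3 channels, 78 frames)"
)
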