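"""Gradient-norm augmentation versus FGSM, and the pocket census.

Trains a Skip-Net briefly on synthetic features, then perturbs one test
image with both crafting methods and runs the adversarial-pocket census.
GNAA's step has exactly the requested Frobenius norm and follows the
gradient's shape; FGSM's step only keeps the gradient's signs.  A
"pocket" is a correctly classified input whose prediction flips under a
beta = 0.01 perturbation while staying essentially identical to the
original (correlation ~ 1).
"""

import numpy as np

import anchoreeg as ae

trials = ae.simulate_dataset(ae.SynthConfig(snr=1.0), n_per_class=15, seed=2)
feats = ae.featurize_trials(
    trials, ae.AnchorSet(), soi_window=ae.SOIWindow(3.0, 5.5)
)
model = ae.build_skipnet(ae.SkipNetSpec(132, 78, 2), seed=2)
ae.train(model, feats[: 20], ae.TrainConfig(max_epochs=5, seed=2))

image, label = feats[25].images[0].values, feats[25].label
gn = ae.gnaa_perturb(model, image, label, magnitude=0.1)
fg = ae.fgsm_perturb(model, image, label, epsilon=0.1)
print(f"GNAA delta Frobenius norm: {np.linalg.norm(gn.delta):.6f} (= magnitude)")
print(f"GNAA distinct delta values: {len(np.unique(gn.delta))}")
print(f"FGSM distinct delta values: {len(np.unique(np.round(fg.delta, 12)))} "
      "(only -eps, 0, +eps)")

report = ae.count_pockets(model, feats[20:], beta=0.01)
q = report.correlation_quantiles()
print(f"census: {report.n_flipped} pockets among {report.n_inputs} "
      "correctly classified inputs")
print(f"original-vs-perturbed correlation median: {q.get('q50', float('nan')):.6f}")

augmented = ae.augment_dataset(model, feats[:20], epsilon=0.1, copies=1, seed=0)
print(f"augmentation: {len(feats[:20])} feature sets -> {len(augmented)}")
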