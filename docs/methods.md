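# Methods

This note records the package's scientific and numerical choices: what
each stage computes, which parameters matter, what the synthetic generator
does and does not emulate, and where genuinely open design points were
settled.

## Anchored-STFT

The transform frames a signal of interest (SOI) of `sL` samples with a set
of anchors (tapered windows) of lengths `aL ∈ {16, 32, 64, 128, 256}`
sharing stride-spaced focal points (`s = 8` by default, half the shortest
anchor, guaranteeing ≥ 50% overlap between adjacent placements of every
anchor). Each anchor produces one spectrogram; short anchors trade
frequency resolution for time resolution and vice versa, and the
classifier consumes all of them.

Framing arithmetic, in the conventions this package fixes:

- **Admissible anchor count.** `K = floor(log2 sL)`. The underlying
  quantity `log(sL)/log 2` is not an integer for general `sL`; the floor
  is taken because an anchor longer than the signal is meaningless.
- **Frame count.** `n_frames = floor(sL / s)`, identical for every anchor
  of the set. For `sL = 625`, `s = 8` this gives 78. The alternative rule
  `1 + (sL − minL)/s` yields the non-integer 77.125 for the same
  configuration; the floor rule is the one consistent with the reference
  count of 78 and is used throughout.
- **Zero padding.** `max(0, s·(n_frames − 1) − sL + aL)` samples, appended
  after the last sample under corner focal points (the default), split
  across both ends under centred focal points (anchor lengths `2^i + 1`,
  implemented but not default).
- **Transform.** Each frame is tapered (Hann by default; Hamming and
  rectangular available), zero-padded to `2·(n_unique_fft − 1)` points
  (512 for the default 257 one-sided bins) and transformed; the one-sided
  magnitude is kept. Value scale is amplitude `|X|` by default, with
  `power` and `log-power` (`log10(|X|² + 1e−12)`) as options.

Band slicing keeps rows with `f_low ≤ f_k ≤ f_high` inclusive — the rule
that yields 22 mu rows (4–15 Hz) and 23 beta rows (19–30 Hz) at bin
spacing 250/512 Hz. The beta block is resized to the mu row count by
spline interpolation along frequency, cubic whenever the block has ≥ 4
rows (smaller blocks fall back to the highest supported order; the
identity case returns the input unchanged). Per channel the band blocks
are stacked mu-above-beta, channels stacked in input order (C3, Cz, C4);
the layout is recorded per image so downstream code need not assume it.
Each image is min–max normalized to [0, 1] (`none` and `zscore`
available); bounded inputs stabilize training.

## Skip-Net

Architecture per image (`N_h × N_t`): conv `N_h × 1` × 16 filters → batch
norm → ReLU → conv `1 × 3` × 16, same padding → batch norm → ReLU → add
(first ReLU + second ReLU) → dense 128 → ReLU → dropout 0.5 → dense
`n_classes` → softmax. Choices the architecture description leaves open
were fixed as: conv → BN → ReLU ordering; He-uniform weight
initialization (seeded), BN scale 1 / shift 0; "momentum 0.9" read as
Adam's first-moment decay `β1` (with `β2 = 0.999`); the L2 penalty (0.01
× sum of squared weights) applied to convolution and dense weights only,
not biases or BN parameters; dropout and L2 active simultaneously.
Training runs the fixed epoch budget with the stepped learning-rate
schedule `0.01 · 0.5^floor(epoch/5)` — no early stopping. Every anchor
image is an independent training example carrying its trial's label;
trials are kept whole across train/test splits so no trial leaks across.

The implementation is plain numpy with a hand-written backward pass
(verified against central finite differences at 1e−4 relative error on a
downsized model). Batch norm uses batch statistics in training and
exponential running statistics (momentum 0.1) in inference. In inference
mode examples are independent, so the batched input-gradient equals the
per-example loop — the property the augmentation module relies on.

## GNAA

`x_new = x + ε · g/‖g‖_F` with `g = ∂cost/∂x`, where cost is the
cross-entropy data term only, evaluated in inference mode (regularizers
have no input gradient; dropout off, BN in evaluation statistics).
Gradients are taken at the original input; perturbation is single-step.
A gradient with Frobenius norm below 1e−12 has no direction and is an
error for a single perturbation, a logged pass-through in bulk operations
(a well-trained softmax saturates on easy examples and genuinely zeroes
the input gradient in float64). The crafting budget for the pocket census
defaults to β = 0.01; the augmentation step size ε is not similarly
pinned by the method and defaults to 0.1, exposed in API and CLI. The
census reports the correlation distribution between originals and
perturbed inputs rather than thresholding "indistinguishability".
Augmentation follows the single train → augment → retrain protocol; the
retrained model starts from the same seeded initialization.

## Voting and metrics

The anchor count N is odd by construction (enforced at AnchorSet and
FeatureSet level), so two-class votes cannot tie. Multi-class mode ties
are broken by the largest summed softmax probability among tied classes
and flagged. Kappa uses the balanced chance level `1/n_classes`, matching
how it accompanies every reference accuracy; an explicit chance level can
be passed for unbalanced sets.

## Synthetic ERD/ERS generator

Each channel is `osc_scale · (A_mu·env_mu·sin(2π f_mu t + φ) +
A_beta·env_beta·sin(2π f_beta t + ψ)) + n(t)`, with `n(t)` unit-RMS
1/f-shaped Gaussian noise (frequency-domain shaping, exponent 1 by
default, DC removed) and phases uniform per trial and channel. During the
motor-imagery window (3–5.5 s of an 8 s trial) the channel contralateral
to the labelled hand (right → C3, left → C4) has mu amplitude ×(1 −
erd_depth) and beta amplitude ×(1 + ers_gain); the envelopes ramp with
0.25 s raised cosines because abrupt edges splatter broadband energy
across both bands. `osc_scale` sets the baseline oscillatory RMS to `snr`
times the noise RMS.

Reference conditions (the defaults): fs 250 Hz, f_mu 10 Hz, f_beta
22 Hz, amplitude ratio 2:1 mu:beta, erd_depth 0.6, ers_gain 0.5, snr 5.
These make the task clearly learnable — a linear probe on the feature
images already separates the classes — which is the intended regime for
validating the pipeline's mechanics. What the generator does *not*
emulate: spatially correlated noise across electrodes, ocular/muscular
artifacts, frequency drift and bursting of real rhythms,
between-subject variability, or volume conduction. Passing tests
therefore validate the pipeline's correctness and trainability, not its
accuracy on recorded EEG.

Determinism: per-trial RNG substreams are spawned from the dataset seed,
so any subset regenerates bit-identically.

## Problem sizes in tests and checks

The suite's behavioural checks run at desk scale, chosen as the smallest
sizes at which each property is stable: end-to-end decoding uses 100
trials per class, an 80/20 stratified trial-level split and a 60-epoch
budget (the learning-rate schedule has decayed by 2^−12 there and
training has converged), median over 3 seeds; the augmentation
robustness comparison uses 50 trials per class at snr 1, 40 epochs, 2
trainings per seed over 5 seeds; transform-vs-DFT equivalence uses 50
random signals of ≤ 512 samples against an O(n²) brute-force Fourier sum
at 1e−9 relative tolerance.

## Known limitations

- The EDF writer is a fixture generator (one data record, int16,
  annotation channel); it is not a general exporter. Reading goes through
  mne and is limited by int16 quantization, not bit-exact (the HDF5 trial
  archive is the lossless path).
- The numpy network is single-threaded and sized for the 132 × 78 inputs;
  it is not a general deep-learning substrate.
- `band_power` is an internal validation helper; only ratios between
  windows/channels/configurations are meaningful, not absolute units.
- Center-focal framing is implemented and tested for shape consistency
  but the decoding experiments all use corner focal points.
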