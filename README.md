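# anchoreeg

Motor-imagery EEG decoding for brain–computer interfaces: anchored-STFT
multi-resolution feature extraction, gradient-norm adversarial augmentation
(GNAA), a shallow skip-connection CNN (Skip-Net), and majority-vote
inference — plus a synthetic ERD/ERS generator so the whole pipeline can be
exercised and validated without recorded EEG.

## The problem and the method

Imagined hand movement produces an event-related desynchronization (ERD, a
mu-band power drop) and synchronization (ERS, a beta-band power rise) over
the motor cortex contralateral to the hand. Decoding these signatures from
a few noisy electrodes (C3, Cz, C4) is the core classification task of
motor-imagery BCIs.

**Anchored-STFT.** A conventional STFT fixes one window length and hence
one time–frequency resolution. The anchored-STFT slides *K anchors* —
windows of lengths `aL^i = 2^i` sharing stride-spaced focal points — over
the signal of interest (SOI) of length `sL`, producing one spectrogram per
anchor length (`K = log(sL)/log 2` bounds the usable lengths). All anchors
share the same `floor(sL/s)` frame positions; trailing zero-padding of
`s·(frames−1) − sL + aL` samples makes the long anchors fit. For the
reference configuration — 2.5 s at 250 Hz (625 samples), anchors
{16, 32, 64, 128, 256}, stride 8, 257 one-sided frequency points — each
anchor yields a 257 × 78 spectrogram; the mu band (4–15 Hz, 22 rows) and
beta band (19–30 Hz, 23 rows, cubically resized to 22) are stacked per
channel, and the three channel blocks are stacked into a 132 × 78 image,
five images per trial.

**Skip-Net.** Each image is classified by a small CNN: a conv layer of 16
kernels `N_h × 1` (collapsing the frequency rows), batch norm, ReLU; a conv
layer of 16 kernels `1 × 3` with same padding, batch norm, ReLU; the two
ReLU outputs are added (the skip connection); then a 128-unit dense layer
with 50% dropout and a softmax. Training uses Adam (first-moment decay
0.9), initial learning rate 0.01 halved every 5 epochs, L2 penalty 0.01,
mini-batches of 200, up to 200 epochs. The network is implemented directly
on numpy, including the backward pass, and is reproducible from a seed.

**GNAA.** With a trained network, a training input is perturbed one step
along the Frobenius-normalized cost gradient,
`x_new = x + ε · (∂cost/∂x) / ‖∂cost/∂x‖_F`, which points toward the
decision boundary while preserving the gradient's per-feature structure
(FGSM, `x + ε·sign(∂cost/∂x)`, is included as the comparator). The same
step at budget β = 0.01 defines *adversarial pockets*: correctly
classified inputs whose prediction flips while remaining correlated
`r ≈ 1` with the original. Augmented copies (label preserved) enlarge the
training set before retraining.

**Inference.** Each of the N (odd) anchor images votes with its predicted
class; the trial label is the majority, with multi-class mode ties broken
by summed softmax probability. Quality is reported as accuracy and
`kappa = (accuracy − 1/n_classes) / (1 − 1/n_classes)`.

## Worked example

`python examples/02_anchored_stft_features.py` prints the full framing
arithmetic of the reference configuration:

```
SOI: 625 samples from a 2.5 s window at 250 Hz
max admissible anchors K = 9
anchor locations per SOI = 78
anchor  16: overlap   8, zero-padding   7, spectrogram (257, 78)
anchor 256: overlap 248, zero-padding 247, spectrogram (257, 78)
mu slice  (4-15 Hz): (22, 78)
beta slice (19-30 Hz): (23, 78)
feature images: 5 per SOI, each 132 x 78 (22 rows x 2 bands x 3 channels, 78 frames)
```

625 samples framed at stride 8 give 78 anchor locations; every anchor
length produces the same 257 × 78 spectrogram grid, and stacking the two
band slices over three channels yields the five 132 × 78 classifier
inputs. `python examples/03_train_and_decode.py` then trains on synthetic
trials and reports held-out voted performance:

```
trained parameters: 163106
voted test accuracy: 1.000
kappa: 1.000
```

The other examples demonstrate the ERD/ERS structure of the generator
(`01`) and GNAA crafting, FGSM contrast and the pocket census (`04`). A
thin CLI mirrors the library (`anchoreeg simulate | featurize | train |
augment | pockets | predict | evaluate | run`).

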