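"""Synthetic motor-imagery EEG with controllable ERD/ERS structure.

During imagined hand movement the sensorimotor cortex contralateral to the
hand shows an event-related desynchronization (ERD) — a drop in mu-band
oscillation amplitude — together with an event-related synchronization
(ERS) — a rise in beta-band amplitude.  This generator emulates exactly
that structure on a three-electrode montage (C3, Cz, C4) over 1/f
background noise, so every downstream stage (featurization, training,
augmentation, voting) can be exercised and validated without recorded EEG.

Each channel is the sum of a mu sinusoid, a beta sinusoid (random phases
per trial) and 1/f-filtered Gaussian noise.  During the motor-imagery
window the channel contralateral to the labelled hand (right hand -> C3,
left hand -> C4) has its mu amplitude multiplied by ``1 - erd_depth`` and
its beta amplitude by ``1 + ers_gain``; the modulation switches on and off
through 0.25 s raised-cosine ramps (abrupt edges would splatter broadband
energy across both bands).  Oscillation amplitudes are scaled so the
baseline oscillatory RMS is ``snr`` times the noise RMS.

The generator is fully reproducible: the same config and seed give
bit-identical trials, and per-trial substreams are spawned so any subset
of a dataset can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LabelError
from .signal_core import Trial, TrialSet

__all__ = ["SynthConfig", "simulate_trial", "simulate_dataset", "band_power"]

#: Standard motor topography: the hand maps to the opposite hemisphere.
CONTRALATERAL = {"right_hand": "C3", "left_hand": "C4"}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Defaults are the package's reference desk-scale conditions: 8 s trials
    at 250 Hz with the motor-imagery window at 3-5.5 s, a 10 Hz mu and a
    22 Hz beta oscillation, ERD depth 0.6, ERS gain 0.5 and an oscillation
    to noise amplitude ratio of 5.
    """

    fs: float = 250.0
    channel_names: tuple[str, ...] = ("C3", "Cz", "C4")
    trial_seconds: float = 8.0
    mi_window: tuple[float, float] = (3.0, 5.5)
    classes: tuple[str, ...] = ("left_hand", "right_hand")
    mu_freq: float = 10.0
    beta_freq: float = 22.0
    base_mu_amp: float = 1.0
    base_beta_amp: float = 0.5
    erd_depth: float = 0.6
    ers_gain: float = 0.5
    noise_exponent: float = 1.0
    snr: float = 5.0
    ramp_seconds: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.ers_gain < 0:
            raise ValueError("ers_gain must be >= 0")
        if not 4 <= self.mu_freq <= 15:
            raise ValueError("mu_freq must lie in the 4-15 Hz mu band")
        if not 19 <= self.beta_freq <= 30:
            raise ValueError("beta_freq must lie in the 19-30 Hz beta band")
        if self.mi_window[1] <= self.mi_window[0]:
            raise ValueError("mi_window end must exceed its start")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))

    @property
    def class_names(self) -> dict[int, str]:
        return dict(enumerate(self.classes))

    def label_index(self, label) -> int:
        if isinstance(label, (int, np.integer)):
            if not 0 <= label < len(self.classes):
                raise LabelError(f"label {label} outside 0..{len(self.classes) - 1}")
            return int(label)
        try:
            return self.classes.index(label)
        except ValueError:
            raise LabelError(f"unknown class {label!r}; know {self.classes}")


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS noise with a |f|^-exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    noise = np.fft.irfft(spectrum * shaping, n=n)
    return noise / noise.std()


def _modulation(cfg: SynthConfig, t: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicative envelope: 1 outside the MI window, ``factor`` inside,
    with raised-cosine ramps of cfg.ramp_seconds at both edges."""
    t0, t1 = cfg.mi_window
    ramp = cfg.ramp_seconds
    r = np.zeros_like(t)
    inside = (t >= t0 + ramp) & (t <= t1 - ramp)
    r[inside] = 1.0
    up = (t >= t0) & (t < t0 + ramp)
    r[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / ramp))
    down = (t > t1 - ramp) & (t <= t1)
    r[down] = 0.5 * (1 - np.cos(np.pi * (t1 - t[down]) / ramp))
    return 1.0 + (factor - 1.0) * r


def simulate_trial(cfg: SynthConfig, label, rng: np.random.Generator) -> Trial:
    """One labelled trial: oscillations + 1/f noise, ERD/ERS on the
    contralateral channel during the MI window."""
    li = cfg.label_index(label)
    class_name = cfg.classes[li]
    target = CONTRALATERAL.get(class_name)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    # Oscillatory amplitude scale making baseline osc RMS = snr * noise RMS.
    base_rms = np.sqrt(cfg.base_mu_amp**2 / 2 + cfg.base_beta_amp**2 / 2)
    osc_scale = cfg.snr / base_rms if base_rms > 0 else 0.0

    data = np.empty((len(cfg.channel_names), n))
    for c, ch in enumerate(cfg.channel_names):
        phase_mu = rng.uniform(0, 2 * np.pi)
        phase_beta = rng.uniform(0, 2 * np.pi)
        mu_env = np.ones_like(t)
        beta_env = np.ones_like(t)
        if ch == target:
            mu_env = _modulation(cfg, t, 1.0 - cfg.erd_depth)
            beta_env = _modulation(cfg, t, 1.0 + cfg.ers_gain)
        osc = cfg.base_mu_amp * mu_env * np.sin(
            2 * np.pi * cfg.mu_freq * t + phase_mu
        ) + cfg.base_beta_amp * beta_env * np.sin(
            2 * np.pi * cfg.beta_freq * t + phase_beta
        )
        noise = _one_over_f_noise(rng, n, cfg.noise_exponent)
        data[c] = osc_scale * osc + noise

    return Trial(
        data=data,
        fs=cfg.fs,
        channel_names=list(cfg.channel_names),
        label=li,
        trial_id=f"synth-{class_name}",
    )


def simulate_dataset(cfg: SynthConfig, n_per_class: int, seed: int | None = None) -> TrialSet:
    """A balanced TrialSet of ``n_per_class`` trials per class.

    Per-trial RNG substreams are spawned from the seed, so regenerating
    with the same seed reproduces every trial bit-exactly regardless of
    how many are drawn.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if seed is None:
        seed = cfg.seed
    n_classes = len(cfg.classes)
    streams = np.random.SeedSequence(seed).spawn(n_per_class * n_classes)
    trials = []
    k = 0
    for i in range(n_per_class):
        for li in range(n_classes):
            rng = np.random.default_rng(streams[k])
            trial = simulate_trial(cfg, li, rng)
            trial.trial_id = f"synth-{i:04d}-{cfg.classes[li]}"
            trials.append(trial)
            k += 1
    return TrialSet(trials, cfg.class_names)


def band_power(trial: Trial, channel: str, band, window) -> float:
    """Mean squared band-limited spectral amplitude over a time window.

    Computed from a single-anchor spectrogram of the windowed signal (the
    anchor is the largest power of two fitting the window, slid at half
    its length).  Used to verify ERD/ERS structure; only relative
    comparisons between windows/channels/configs are meaningful.
    """
    from .anchored_stft import AnchorSet, band_slice, compute_spectrogram
    from .signal_core import SOIWindow, extract_soi

    if not isinstance(window, SOIWindow):
        window = SOIWindow(*window)
    seg = extract_soi(trial, window)
    signal = seg.channel(channel)
    anchor = 2 ** int(np.floor(np.log2(len(signal))))
    aset = AnchorSet(
        lengths=(anchor,), stride=max(anchor // 2, 1), n_unique_fft=anchor // 2 + 1
    )
    spec = compute_spectrogram(signal, trial.fs, anchor, aset, channel)
    block = band_slice(spec, band)
    return float(np.mean(block**2))
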