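"""Anchored short-time Fourier transform and feature-image assembly.

A conventional STFT slides a single fixed-length window over the signal, so
every location of the spectrogram carries the same time-frequency
resolution.  The anchored STFT instead defines a set of *anchors* — windows
of different lengths sharing the same stride-spaced focal points — and
computes one spectrogram per anchor length.  Short anchors give fine time /
coarse frequency resolution, long anchors the reverse; the classifier later
votes over the per-anchor predictions.

Framing arithmetic for an SOI of length ``sL`` with stride ``s``:

* maximum admissible anchor count  K = floor(log2(sL));
* overlap between adjacent placements of an anchor of length aL is
  ``aL - s``;
* every anchor in a set is slid over the same ``floor(sL / s)`` positions,
  achieved by zero-padding the signal by
  ``s * (n_positions - 1) - sL + aL`` samples (trailing for corner focal
  points, split across both ends for centred ones).

With the reference configuration — a 625-sample SOI at 250 Hz, anchors
{16, 32, 64, 128, 256}, stride 8, 257 one-sided frequency points — each
anchor yields a 257 x 78 spectrogram; slicing the mu band (4-15 Hz,
22 rows) and beta band (19-30 Hz, 23 rows, cubically resized to 22),
stacking both bands for each of three channels, gives five 132 x 78
feature images per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import get_window

from .errors import (
    EmptyBandError,
    InvalidLengthError,
    InvalidStrideError,
    TooFewRowsError,
    UnknownAnchorError,
)
from .signal_core import Trial

__all__ = [
    "AnchorSet",
    "Spectrogram",
    "BandSpec",
    "FeatureImage",
    "FeatureSet",
    "MU_BAND",
    "BETA_BAND",
    "max_num_anchors",
    "anchor_overlap",
    "num_anchor_positions",
    "zero_padding_length",
    "compute_spectrogram",
    "band_slice",
    "resize_band",
    "featurize_soi",
    "featurize_trials",
    "write_feature_archive",
    "read_feature_archive",
]


def _is_pow2(n: int) -> bool:
    return n >= 2 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_low, f_high] in Hz, inclusive at both ends."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise EmptyBandError(
                f"band {self.name!r}: need 0 <= f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )


#: Operational mu band: 4-15 Hz (22 rows at 250 Hz / 512-point transform).
MU_BAND = BandSpec("mu", 4.0, 15.0)
#: Operational beta band: 19-30 Hz (23 rows at the same resolution).
BETA_BAND = BandSpec("beta", 19.0, 30.0)


@dataclass(frozen=True)
class AnchorSet:
    """Anchor lengths, stride and framing conventions.

    ``lengths`` must be powers of two under ``focal='corner'`` (or powers
    of two plus one under ``focal='center'``) and odd in number, because the
    final prediction is a majority vote over the per-anchor classifiers.
    The default stride is half the shortest anchor, guaranteeing at least
    50% overlap between adjacent placements of every anchor.
    """

    lengths: tuple[int, ...] = (16, 32, 64, 128, 256)
    stride: int | None = None
    focal: str = "corner"
    window_shape: str = "hann"
    n_unique_fft: int = 257

    def __post_init__(self) -> None:
        lengths = tuple(int(v) for v in self.lengths)
        object.__setattr__(self, "lengths", lengths)
        if self.focal not in ("corner", "center"):
            raise InvalidLengthError(f"unknown focal convention {self.focal!r}")
        if self.window_shape not in ("hann", "hamming", "rectangular"):
            raise InvalidLengthError(f"unknown window {self.window_shape!r}")
        for L in lengths:
            ok = _is_pow2(L) if self.focal == "corner" else _is_pow2(L - 1)
            if not ok:
                raise InvalidLengthError(
                    f"anchor length {L} invalid for focal={self.focal!r}"
                )
        if len(lengths) % 2 == 0:
            raise InvalidLengthError(
                "number of anchors must be odd (majority voting)"
            )
        if self.stride is None:
            min_l = min(lengths)
            default = min_l // 2 if self.focal == "corner" else (min_l - 1) // 2
            object.__setattr__(self, "stride", max(default, 1))
        if self.stride < 1:
            raise InvalidStrideError("stride must be >= 1")
        if self.n_unique_fft < max(lengths) // 2 + 1:
            raise InvalidLengthError(
                f"n_unique_fft={self.n_unique_fft} cannot represent an "
                f"anchor of {max(lengths)} samples"
            )

    @property
    def n_anchors(self) -> int:
        return len(self.lengths)

    @property
    def nfft(self) -> int:
        """Two-sided transform length, 2 * (n_unique_fft - 1)."""
        return 2 * (self.n_unique_fft - 1)

    def taper(self, length: int) -> np.ndarray:
        name = {"hann": "hann", "hamming": "hamming", "rectangular": "boxcar"}[
            self.window_shape
        ]
        return get_window(name, length, fftbins=True)


@dataclass
class Spectrogram:
    """One anchor's magnitude (or power) spectrogram of one channel."""

    values: np.ndarray  # (n_freq, n_frames)
    bin_freqs: np.ndarray  # Hz per row
    frame_times: np.ndarray  # seconds per column
    anchor_length: int
    channel_name: str = ""

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureImage:
    """One anchor's stacked (channel x band) spectro-temporal image.

    ``row_layout`` records, per vertical block, the tuple
    (channel_name, band_name, row_start, row_stop) so downstream code can
    recover which rows belong to which channel/band.
    """

    values: np.ndarray  # (N_h, N_t)
    anchor_length: int
    row_layout: list[tuple[str, str, int, int]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FeatureSet:
    """All anchor images of one trial, plus its label."""

    images: list[FeatureImage]
    label: int
    trial_id: str = ""

    def __post_init__(self) -> None:
        if len(self.images) % 2 == 0:
            raise InvalidLengthError(
                "a FeatureSet must hold an odd number of anchor images"
            )

    @property
    def n_anchors(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# Framing arithmetic
# ---------------------------------------------------------------------------

def max_num_anchors(sL: int) -> int:
    """Maximum number of anchors for a signal of ``sL`` samples.

    floor(log2(sL)): the longest admissible anchor is the largest power of
    two not exceeding the signal.
    """
    if sL < 2:
        raise InvalidLengthError(f"signal of {sL} samples admits no anchors")
    return int(sL).bit_length() - 1


def anchor_overlap(anchor_len: int, stride: int) -> int:
    """Samples shared by adjacent placements of one anchor: aL - stride."""
    if stride > anchor_len:
        raise InvalidStrideError(
            f"stride {stride} exceeds anchor length {anchor_len}"
        )
    return anchor_len - stride


def num_anchor_positions(sL: int, stride: int) -> int:
    """Number of anchor locations (frames) for a signal of ``sL`` samples.

    floor(sL / stride); the same count applies to every anchor of the set
    (zero-padding makes the long anchors fit).  625 samples at stride 8
    give 78 locations.
    """
    if stride < 1 or stride > sL:
        raise InvalidStrideError(f"stride {stride} invalid for signal {sL}")
    return sL // stride


def zero_padding_length(
    stride: int, n_positions: int, sL: int, anchor_len: int
) -> int:
    """Padding needed so ``n_positions`` frames of ``anchor_len`` fit.

    stride * (n_positions - 1) - sL + anchor_len, clamped at zero.  Applied
    after the last sample under corner focal points, split across both ends
    under centred ones.
    """
    return max(0, stride * (n_positions - 1) - sL + anchor_len)


# ---------------------------------------------------------------------------
# Spectrogram computation
# ---------------------------------------------------------------------------

def _frames(signal: np.ndarray, anchor_len: int, aset: AnchorSet) -> np.ndarray:
    """(n_positions, anchor_len) matrix of zero-padded signal segments."""
    sL = len(signal)
    n_pos = num_anchor_positions(sL, aset.stride)
    pad = zero_padding_length(aset.stride, n_pos, sL, anchor_len)
    if aset.focal == "corner":
        padded = np.concatenate([signal, np.zeros(pad)])
        starts = np.arange(n_pos) * aset.stride
    else:
        half = (anchor_len - 1) // 2
        padded = np.concatenate([np.zeros(half), signal, np.zeros(pad)])
        starts = np.arange(n_pos) * aset.stride  # focal point k*stride
    idx = starts[:, None] + np.arange(anchor_len)[None, :]
    return padded[idx]


def compute_spectrogram(
    signal: np.ndarray,
    fs: float,
    anchor_len: int,
    anchor_set: AnchorSet,
    channel_name: str = "",
    scale: str = "amplitude",
) -> Spectrogram:
    """Spectrogram of a 1-D signal for one anchor length of a set.

    Each of the set's ``floor(sL / stride)`` frames takes ``anchor_len``
    samples from the zero-padded signal, applies the set's taper,
    zero-pads to the two-sided transform length ``2 * (n_unique_fft - 1)``
    and keeps the one-sided magnitude (``scale='amplitude'``), squared
    magnitude (``'power'``) or ``log10(|X|^2 + 1e-12)`` (``'log-power'``).
    """
    if anchor_len not in anchor_set.lengths:
        raise UnknownAnchorError(
            f"anchor {anchor_len} not in set {anchor_set.lengths}"
        )
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise InvalidLengthError("compute_spectrogram expects a 1-D signal")
    if len(signal) < anchor_set.stride:
        raise InvalidStrideError("signal shorter than one stride")

    segs = _frames(signal, anchor_len, anchor_set) * anchor_set.taper(anchor_len)
    spec = np.abs(np.fft.rfft(segs, n=anchor_set.nfft, axis=1)).T
    if scale == "power":
        spec = spec**2
    elif scale == "log-power":
        spec = np.log10(spec**2 + 1e-12)
    elif scale != "amplitude":
        raise InvalidLengthError(f"unknown scale {scale!r}")

    n_pos = spec.shape[1]
    bin_freqs = np.arange(anchor_set.n_unique_fft) * fs / anchor_set.nfft
    frame_times = np.arange(n_pos) * anchor_set.stride / fs
    return Spectrogram(spec, bin_freqs, frame_times, anchor_len, channel_name)


def band_slice(spec: Spectrogram, band: BandSpec) -> np.ndarray:
    """Rows of the spectrogram whose bin frequency lies in the band.

    Selection is inclusive at both edges: f_low <= f_k <= f_high.  At
    250 Hz with a 512-point transform (bin spacing 250/512 Hz) the mu band
    4-15 Hz selects 22 rows and the beta band 19-30 Hz selects 23.
    """
    mask = (spec.bin_freqs >= band.f_low) & (spec.bin_freqs <= band.f_high)
    if not mask.any():
        raise EmptyBandError(
            f"band {band.name!r} [{band.f_low}, {band.f_high}] Hz selects no rows"
        )
    return spec.values[mask]


def resize_band(block: np.ndarray, target_rows: int) -> np.ndarray:
    """Resample a band block along its frequency axis by cubic interpolation.

    Every time column is interpolated independently onto ``target_rows``
    uniformly spaced points spanning the original row range.  Blocks with
    fewer than four rows fall back to the highest spline order they
    support.  ``target_rows == r`` returns the input unchanged.
    """
    block = np.asarray(block, dtype=np.float64)
    r = block.shape[0]
    if target_rows < 1:
        raise TooFewRowsError("target_rows must be >= 1")
    if r == target_rows:
        return block.copy()
    if r < 2:
        raise TooFewRowsError(f"cannot interpolate a {r}-row block")
    x_old = np.linspace(0.0, 1.0, r)
    x_new = np.linspace(0.0, 1.0, target_rows)
    spline = make_interp_spline(x_old, block, k=min(3, r - 1), axis=0)
    return spline(x_new)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def _normalize_image(values: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return values
    if how == "minmax":
        lo, hi = values.min(), values.max()
        if hi - lo < 1e-30:
            return np.zeros_like(values)
        return (values - lo) / (hi - lo)
    if how == "zscore":
        sd = values.std()
        if sd < 1e-30:
            return np.zeros_like(values)
        return (values - values.mean()) / sd
    raise InvalidLengthError(f"unknown normalization {how!r}")


def featurize_soi(
    soi: Trial,
    anchor_set: AnchorSet,
    bands: list[BandSpec] | None = None,
    common_rows: int = 22,
    scale: str = "amplitude",
    normalize: str = "minmax",
) -> FeatureSet:
    """Turn one SOI into the per-anchor stack of feature images.

    For each anchor length: every channel is transformed to a spectrogram,
    each band is sliced out and resized to ``common_rows``, the band blocks
    are stacked vertically (band order as given) within each channel, and
    the channel blocks are stacked in channel order.  The resulting image
    has ``common_rows * n_bands * n_channels`` rows and one column per
    anchor location; with the reference configuration that is 132 x 78,
    and five anchors give five images per SOI.
    """
    if bands is None:
        bands = [MU_BAND, BETA_BAND]
    if not bands:
        raise EmptyBandError("at least one band is required")
    images: list[FeatureImage] = []
    for anchor_len in anchor_set.lengths:
        blocks: list[np.ndarray] = []
        layout: list[tuple[str, str, int, int]] = []
        row = 0
        for ch, name in enumerate(soi.channel_names):
            spec = compute_spectrogram(
                soi.data[ch], soi.fs, anchor_len, anchor_set, name, scale
            )
            for band in bands:
                blk = resize_band(band_slice(spec, band), common_rows)
                blocks.append(blk)
                layout.append((name, band.name, row, row + common_rows))
                row += common_rows
        values = _normalize_image(np.vstack(blocks), normalize)
        images.append(FeatureImage(values, anchor_len, layout))
    return FeatureSet(images, soi.label, soi.trial_id)


def featurize_trials(
    trials,
    anchor_set: AnchorSet,
    soi_window=None,
    bands: list[BandSpec] | None = None,
    common_rows: int = 22,
    scale: str = "amplitude",
    normalize: str = "minmax",
) -> list[FeatureSet]:
    """Featurize every trial of a TrialSet (optionally cutting an SOI first)."""
    from .signal_core import extract_soi

    out = []
    for trial in trials:
        soi = extract_soi(trial, soi_window) if soi_window is not None else trial
        out.append(
            featurize_soi(soi, anchor_set, bands, common_rows, scale, normalize)
        )
    return out


# ---------------------------------------------------------------------------
# Feature archive
# ---------------------------------------------------------------------------

def write_feature_archive(feature_sets: list[FeatureSet], path, config: dict | None = None) -> None:
    """Store feature sets as HDF5: ``/features`` (n_trials x N x N_h x N_t),
    ``/labels``, ``trial_ids`` and the featurization config (JSON attr)."""
    import json

    import h5py

    arr = np.stack(
        [np.stack([im.values for im in fs.images]) for fs in feature_sets]
    )
    anchor_lengths = [im.anchor_length for im in feature_sets[0].images]
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=arr)
        f.create_dataset(
            "labels", data=np.array([fs.label for fs in feature_sets], dtype=np.int64)
        )
        f.attrs["trial_ids"] = [fs.trial_id for fs in feature_sets]
        f.attrs["anchor_lengths"] = anchor_lengths
        f.attrs["config"] = json.dumps(config or {})


def read_feature_archive(path) -> tuple[list[FeatureSet], dict]:
    """Inverse of :func:`write_feature_archive`."""
    import json

    import h5py

    from .errors import FormatError

    with h5py.File(path, "r") as f:
        for name in ("features", "labels"):
            if name not in f:
                raise FormatError(f"feature archive missing dataset '/{name}'")
        arr = f["features"][...]
        labels = f["labels"][...]
        trial_ids = [str(t) for t in f.attrs.get("trial_ids", [])]
        anchor_lengths = list(f.attrs.get("anchor_lengths", []))
        config = json.loads(f.attrs.get("config", "{}"))
    if not trial_ids:
        trial_ids = [f"trial-{i:04d}" for i in range(arr.shape[0])]
    if not anchor_lengths:
        anchor_lengths = [0] * arr.shape[1]
    sets = []
    for i in range(arr.shape[0]):
        images = [
            FeatureImage(arr[i, a], int(anchor_lengths[a]))
            for a in range(arr.shape[1])
        ]
        sets.append(FeatureSet(images, int(labels[i]), trial_ids[i]))
    return sets, config
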