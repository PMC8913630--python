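"""EEG trial containers, signal-of-interest extraction, and trial I/O.

The raw unit of data is the :class:`Trial`: a channels x samples matrix in
microvolts with a sampling rate, ordered channel names and an integer class
label.  A :class:`TrialSet` is a homogeneous collection of trials sharing
sampling rate and montage.  Trials enter the package either from EDF/EDF+
recordings (via :func:`read_edf`) or from the package's own HDF5 trial
archive (:func:`read_trial_archive` / :func:`write_trial_archive`), which
round-trips floating-point data bit-exactly.

Time convention: trial-relative seconds; sample index = round(t * fs);
half-open sample interval [start, start + n).  With fs = 250 Hz a
2.5 s window therefore yields exactly 625 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import (
    ChannelError,
    FormatError,
    InvalidWindowError,
    LabelError,
    OutOfRangeError,
)

__all__ = [
    "Trial",
    "TrialSet",
    "SOIWindow",
    "extract_soi",
    "read_trial_archive",
    "write_trial_archive",
    "read_edf",
    "write_edf_fixture",
]


@dataclass
class Trial:
    """One multichannel EEG segment with its class label.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per row of ``data``, in row order.
    label : int
        Dense class identifier (>= 0).
    trial_id : str
        Stable identifier used for split bookkeeping.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    label: int
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("trial needs at least one channel and one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if self.label < 0:
            raise LabelError("labels are dense non-negative integers")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return the 1-D signal of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ChannelError(f"channel {name!r} not in {self.channel_names}")
        return self.data[idx]


@dataclass
class TrialSet:
    """An ordered, homogeneous collection of trials.

    All trials share sampling rate, channel count and channel names; every
    label that occurs is a key of ``class_names``.
    """

    trials: list[Trial]
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trials:
            ref = self.trials[0]
            for t in self.trials:
                if t.fs != ref.fs:
                    raise ValueError("trials with mixed sampling rates")
                if t.channel_names != ref.channel_names:
                    raise ValueError("trials with mixed channel layouts")
            for t in self.trials:
                if t.label not in self.class_names:
                    raise LabelError(
                        f"label {t.label} missing from class_names map"
                    )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def channel_names(self) -> list[str]:
        return self.trials[0].channel_names

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=np.int64)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "TrialSet":
        """A new TrialSet holding the trials at ``indices`` (order kept)."""
        return TrialSet([self.trials[i] for i in indices], dict(self.class_names))


@dataclass(frozen=True)
class SOIWindow:
    """The signal-of-interest window, in trial-relative seconds."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise InvalidWindowError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )

    def n_samples(self, fs: float) -> int:
        """SOI length in samples: round((t_end - t_start) * fs)."""
        return int(round((self.t_end - self.t_start) * fs))


def extract_soi(trial: Trial, window: SOIWindow) -> Trial:
    """Cut the signal-of-interest out of a trial.

    The window is mapped to samples with start = round(t_start * fs) and
    length round((t_end - t_start) * fs); channel order and label are
    preserved.  A 3-5.5 s window at 250 Hz yields 625 samples.
    """
    fs = trial.fs
    start = int(round(window.t_start * fs))
    n = window.n_samples(fs)
    if window.t_start < 0 or start + n > trial.n_samples:
        raise OutOfRangeError(
            f"window [{window.t_start}, {window.t_end}] s outside trial of "
            f"{trial.duration:.3f} s"
        )
    return Trial(
        data=trial.data[:, start : start + n].copy(),
        fs=fs,
        channel_names=list(trial.channel_names),
        label=trial.label,
        trial_id=trial.trial_id,
    )


# ---------------------------------------------------------------------------
# HDF5 trial archive
# ---------------------------------------------------------------------------

def write_trial_archive(trial_set: TrialSet, path) -> None:
    """Write a TrialSet to the HDF5 trial-archive layout.

    Layout: datasets ``/trials`` (float64, n_trials x n_channels x
    n_samples) and ``/labels`` (int64); root attributes ``fs``,
    ``channel_names``, ``class_names`` and ``trial_ids``.
    """
    data = np.stack([t.data for t in trial_set.trials])
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=data)
        f.create_dataset("labels", data=trial_set.labels)
        f.attrs["fs"] = float(trial_set.fs)
        f.attrs["channel_names"] = list(trial_set.channel_names)
        n_cls = max(trial_set.class_names) + 1 if trial_set.class_names else 0
        f.attrs["class_names"] = [
            trial_set.class_names.get(i, f"class_{i}") for i in range(n_cls)
        ]
        f.attrs["trial_ids"] = [t.trial_id for t in trial_set.trials]


def read_trial_archive(path) -> TrialSet:
    """Read a trial archive written by :func:`write_trial_archive`.

    Raises :class:`~anchoreeg.errors.FormatError` naming the first missing
    dataset or attribute.
    """
    with h5py.File(path, "r") as f:
        for name in ("trials", "labels"):
            if name not in f:
                raise FormatError(f"trial archive missing dataset '/{name}'")
        for attr in ("fs", "channel_names", "class_names"):
            if attr not in f.attrs:
                raise FormatError(f"trial archive missing root attribute {attr!r}")
        data = f["trials"][...]
        labels = f["labels"][...]
        fs = float(f.attrs["fs"])
        channel_names = [str(c) for c in f.attrs["channel_names"]]
        class_list = [str(c) for c in f.attrs["class_names"]]
        trial_ids = [str(t) for t in f.attrs.get("trial_ids", [])]
    if data.ndim != 3:
        raise FormatError("'/trials' must be 3-D (trials x channels x samples)")
    if len(labels) != data.shape[0]:
        raise FormatError("'/labels' length does not match '/trials'")
    if not trial_ids:
        trial_ids = [f"trial-{i:04d}" for i in range(data.shape[0])]
    trials = [
        Trial(data[i], fs, list(channel_names), int(labels[i]), trial_ids[i])
        for i in range(data.shape[0])
    ]
    return TrialSet(trials, {i: n for i, n in enumerate(class_list)})


# ---------------------------------------------------------------------------
# EDF/EDF+
# ---------------------------------------------------------------------------

def read_edf(
    path,
    channel_subset: list[str],
    event_map: dict[str, int],
    trial_seconds: float,
    class_names: dict[int, str] | None = None,
) -> TrialSet:
    """Cut labelled trials from an EDF/EDF+ recording.

    One trial of ``trial_seconds`` duration is cut at the onset of every
    annotation whose description is a key of ``event_map``; the mapped value
    becomes the trial label.  Channels are restricted to and ordered as
    ``channel_subset``.  If no annotation matches, an empty TrialSet is
    returned with a warning.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    missing = [c for c in channel_subset if c not in raw.ch_names]
    if missing:
        raise ChannelError(f"channels {missing} absent from {path}")
    raw.pick(channel_subset)
    raw.reorder_channels(channel_subset)
    fs = float(raw.info["sfreq"])
    # mne scales EEG to volts internally; trials are kept in microvolts
    signal = raw.get_data() * 1e6
    n_per_trial = int(round(trial_seconds * fs))

    trials: list[Trial] = []
    for k, ann in enumerate(raw.annotations):
        desc = str(ann["description"])
        if desc not in event_map:
            continue
        start = int(round(float(ann["onset"]) * fs))
        if start + n_per_trial > signal.shape[1]:
            continue
        trials.append(
            Trial(
                data=signal[:, start : start + n_per_trial],
                fs=fs,
                channel_names=list(channel_subset),
                label=int(event_map[desc]),
                trial_id=f"edf-{k:04d}-{desc}",
            )
        )
    if not trials:
        warnings.warn(f"no annotations in {path} matched the event map")
    if class_names is None:
        class_names = {v: k for k, v in event_map.items()}
    return TrialSet(trials, class_names)


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf_fixture(
    path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    events: list[tuple[float, float, str]],
) -> None:
    """Write a minimal EDF+C file for tests and examples.

    A deliberately small EDF+ writer (one data record holding the whole
    recording, int16 samples, physical unit microvolt, one annotations
    channel carrying the events as time-stamped annotation lists).  It
    produces files that standard EDF readers accept; it is a fixture
    generator, not a general-purpose exporter.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples), microvolts
    events : list of (onset_seconds, duration_seconds, description)
    """
    data = np.asarray(data, dtype=np.float64)
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("one channel name per data row required")
    record_seconds = n_samp / fs

    # Annotation byte stream: the record's time-keeping TAL, then one TAL
    # per event.  \x14 and \x15 are the TAL field separators.
    tal = b"+0\x14\x14\x00"
    for onset, dur, desc in events:
        tal += f"+{onset:g}\x15{dur:g}\x14{desc}\x14\x00".encode("ascii")
    if len(tal) % 2:
        tal += b"\x00"
    ann_samples = max(len(tal) // 2, 60)  # headroom keeps readers happy
    tal = tal.ljust(ann_samples * 2, b"\x00")

    n_signals = n_ch + 1
    header_bytes = 256 * (1 + n_signals)

    # Per-channel physical scaling onto the int16 digital range.
    phys_min, phys_max = [], []
    digital = np.empty((n_ch, n_samp), dtype="<i2")
    for c in range(n_ch):
        lo = float(np.floor(data[c].min() - 1.0))
        hi = float(np.ceil(data[c].max() + 1.0))
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = (data[c] - lo) / (hi - lo) * 65535.0 - 32768.0
        digital[c] = np.round(scaled).astype("<i2")

    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))
        f.write(_edf_field("Startdate 01-JAN-2000 X X X", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(header_bytes, 8))
        f.write(_edf_field("EDF+C", 44))
        f.write(_edf_field(1, 8))  # one data record
        f.write(_edf_field(f"{record_seconds:g}", 8))
        f.write(_edf_field(n_signals, 4))

        labels = list(channel_names) + ["EDF Annotations"]
        for lab in labels:
            f.write(_edf_field(lab, 16))
        for _ in labels:
            f.write(_edf_field("", 80))  # transducer
        for i in range(n_signals):
            f.write(_edf_field("uV" if i < n_ch else "", 8))
        for i in range(n_signals):
            f.write(_edf_field(phys_min[i] if i < n_ch else -1, 8))
        for i in range(n_signals):
            f.write(_edf_field(phys_max[i] if i < n_ch else 1, 8))
        for _ in range(n_signals):
            f.write(_edf_field(-32768, 8))
        for _ in range(n_signals):
            f.write(_edf_field(32767, 8))
        for _ in labels:
            f.write(_edf_field("", 80))  # prefiltering
        for i in range(n_signals):
            f.write(_edf_field(n_samp if i < n_ch else ann_samples, 8))
        for _ in labels:
            f.write(_edf_field("", 32))  # reserved

        f.write(digital.tobytes())
        f.write(tal)
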