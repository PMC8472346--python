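"""Epoch-level preprocessing: filtering, resampling, segmentation, rejection.

The chain mirrors standard evoked-response practice: zero-phase band-pass
(0.5-100 Hz by default), decimation to 200 Hz, segmentation into
stimulus-locked epochs (-100...1000 ms), optional mean-baseline
subtraction over the pre-stimulus interval, and peak-to-peak amplitude
rejection.  Independent-component artifact removal is deliberately an
external hook: component selection is a manual judgement, so this module
only applies a caller-supplied projection.

Epochs travel in a plain HDF5 layout: ``/data`` (trials x channels x
samples), ``/labels`` (strings), attrs ``fs``, ``tmin_ms``,
``participant_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "Epochs",
    "bandpass",
    "resample",
    "epoch",
    "baseline_correct",
    "reject_peak_to_peak",
    "save_epochs",
    "load_epochs",
    "epochs_from_fif",
]


@dataclass
class RawRecording:
    """Continuous multichannel recording with stimulus events."""

    data: np.ndarray  # channels x samples
    fs: float
    channel_ids: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[-1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample {s} outside recording of {n} samples")


@dataclass
class Epochs:
    """Stimulus-locked trials: (n_trials, n_channels, n_samples).

    ``tmin`` is the epoch start relative to stimulus onset in ms
    (negative = pre-stimulus).  The time axis is ``tmin + 1000*i/fs``.
    """

    data: np.ndarray
    fs: float
    tmin: float  # ms
    labels: np.ndarray  # per-trial condition, dtype str
    participant_id: str = ""
    channel_ids: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be trials x channels x samples")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in ms relative to stimulus onset."""
        return self.tmin + 1000.0 * np.arange(self.n_samples) / self.fs

    def select(self, label: str) -> "Epochs":
        keep = self.labels == label
        return replace(self, data=self.data[keep], labels=self.labels[keep])


# ---------------------------------------------------------------------------
# operations


def bandpass(raw: RawRecording, lo: float, hi: float, order: int = 4,
             design: str = "iir") -> RawRecording:
    """Zero-phase band-pass filter (forward-backward).

    Default is a 4th-order Butterworth applied with ``filtfilt``; a
    linear-phase FIR alternative (``design='fir'``) is available.  DC is
    in the stopband, so constant offsets are removed.
    """
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= raw.fs / 2:
        raise ValueError(f"high edge {hi} Hz >= Nyquist ({raw.fs / 2} Hz)")
    if design == "fir":
        numtaps = int(3 * raw.fs / lo) | 1
        taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=raw.fs)
        out = signal.filtfilt(taps, [1.0], raw.data, axis=-1)
    else:
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=raw.fs, output="sos")
        out = signal.sosfiltfilt(sos, raw.data, axis=-1)
    return replace(raw, data=out)


def resample(obj: RawRecording | Epochs, fs_new: float) -> RawRecording | Epochs:
    """Polyphase anti-aliased resampling; event/time bookkeeping rescaled.

    The new sample count is ``round(n * fs_new / fs)`` (endpoint handling
    follows the polyphase grid).  Resampling to the current rate is the
    identity.
    """
    fs_old = obj.fs
    if fs_new == fs_old:
        return obj
    if fs_new > fs_old:
        raise ValueError("upsampling not supported")
    frac = Fraction(fs_new / fs_old).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(obj.data, up, down, axis=-1)
    if isinstance(obj, RawRecording):
        events = [(int(round(s * fs_new / fs_old)), lab) for s, lab in obj.events]
        events = [(min(s, out.shape[-1] - 1), lab) for s, lab in events]
        return replace(obj, data=out, fs=fs_new, events=events)
    return replace(obj, data=out, fs=fs_new)


def epoch(raw: RawRecording, tmin: float, tmax: float,
          participant_id: str = "") -> Epochs:
    """Segment a recording into stimulus-locked epochs.

    ``tmin``/``tmax`` are in ms relative to each event; the window is
    endpoint-inclusive, so -100...1000 ms at 200 Hz gives 221 samples.
    Events whose window exceeds the recording are dropped with a warning.
    """
    if tmin >= tmax:
        raise ValueError("tmin must precede tmax")
    pre = int(round(-tmin * raw.fs / 1000.0))
    post = int(round(tmax * raw.fs / 1000.0))
    n = raw.data.shape[-1]
    trials, labels = [], []
    for s, lab in raw.events:
        if s - pre < 0 or s + post >= n:
            logger.warning("event at sample %d does not fit window, trial dropped", s)
            continue
        trials.append(raw.data[:, s - pre : s + post + 1])
        labels.append(lab)
    if not trials:
        raise ValueError("no events fit the requested epoch window")
    return Epochs(
        data=np.stack(trials),
        fs=raw.fs,
        tmin=-pre * 1000.0 / raw.fs,
        labels=np.array(labels),
        participant_id=participant_id,
        channel_ids=list(raw.channel_ids),
    )


def baseline_correct(epochs: Epochs, t_start: float | None = None,
                     t_end: float = 0.0) -> Epochs:
    """Subtract each trial/channel's mean over the baseline window (ms)."""
    t = epochs.times
    lo = epochs.tmin if t_start is None else t_start
    mask = (t >= lo) & (t <= t_end)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    mean = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return replace(epochs, data=epochs.data - mean)


def reject_peak_to_peak(epochs: Epochs, threshold: float) -> tuple[Epochs, int]:
    """Drop trials where any channel's max-min exceeds ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    p2p = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)
    keep = (p2p <= threshold).all(axis=1)
    n_rejected = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"peak-to-peak threshold {threshold} rejected every trial"
        )
    out = replace(epochs, data=epochs.data[keep], labels=epochs.labels[keep])
    return out, n_rejected


# ---------------------------------------------------------------------------
# I/O


def save_epochs(epochs: Epochs, path: str | Path, extra: dict | None = None) -> None:
    """Write epochs to the package's HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "labels", data=np.array([str(l) for l in epochs.labels], dtype="S")
        )
        if epochs.channel_ids is not None:
            f.create_dataset(
                "channel_ids", data=np.array(epochs.channel_ids, dtype="S")
            )
        f.attrs["fs"] = epochs.fs
        f.attrs["tmin_ms"] = epochs.tmin
        f.attrs["participant_id"] = epochs.participant_id
        for k, v in (extra or {}).items():
            f.attrs[k] = v


def load_epochs(path: str | Path) -> Epochs:
    with h5py.File(path, "r") as f:
        channel_ids = None
        if "channel_ids" in f:
            channel_ids = [c.decode() for c in f["channel_ids"][()]]
        return Epochs(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            tmin=float(f.attrs["tmin_ms"]),
            labels=np.array([l.decode() for l in f["labels"][()]]),
            participant_id=str(f.attrs.get("participant_id", "")),
            channel_ids=channel_ids,
        )


def epochs_from_fif(path: str | Path, participant_id: str = "") -> Epochs:
    """Ingest an MNE epochs FIF file (requires the optional ``mne`` package)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading FIF files requires the 'mne' package") from exc
    ep = mne.read_epochs(str(path), preload=True, verbose="error")
    inv_id = {v: k for k, v in ep.event_id.items()}
    labels = np.array([inv_id[e] for e in ep.events[:, 2]])
    return Epochs(
        data=ep.get_data(copy=True),
        fs=float(ep.info["sfreq"]),
        tmin=float(ep.tmin) * 1000.0,
        labels=labels,
        participant_id=participant_id,
        channel_ids=list(ep.ch_names),
    )
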