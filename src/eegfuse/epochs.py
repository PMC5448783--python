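"""Containers and I/O for continuous and epoched EEG.

An :class:`EpochSet` is the pipeline's central container: a stack of
fixed-length, labelled trials (trial x channel x sample, in microvolts).
A :class:`ContinuousRecording` carries an unsegmented multichannel signal
plus an event list, and is what EDF files are read into.

Persistence conventions: epoch/feature arrays go to NumPy ``.npz``
(compressed), reports and configs to JSON, tables to TSV.  EDF is
read-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt


class ValidationError(ValueError):
    """Invalid input data or parameters; names the offending field."""


class EDFParseError(RuntimeError):
    """Raised when an EDF file cannot be parsed."""


@dataclass
class EpochSet:
    """Labelled EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltages in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class id per trial, values in ``1..K``.
    image_ids : ndarray of int, shape (n_trials,)
        Stimulus identifier per trial; repeated presentations of the same
        stimulus share an id.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    """

    data: np.ndarray
    labels: np.ndarray
    image_ids: np.ndarray
    fs: float
    channel_names: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.image_ids = np.asarray(self.image_ids, dtype=int)
        if self.data.ndim != 3:
            raise ValidationError("data must be trial x channel x sample")
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        n = self.data.shape[0]
        if self.labels.shape != (n,):
            raise ValidationError("labels length must match n_trials")
        if self.image_ids.shape != (n,):
            raise ValidationError("image_ids length must match n_trials")
        if n and self.labels.min() < 1:
            raise ValidationError("labels must be 1-based class ids")
        if not self.channel_names:
            self.channel_names = [f"E{i + 1}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError("channel_names length must match n_channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        """Number of electrodes (rows of each trial matrix)."""
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        """Samples per trial (columns of each trial matrix)."""
        return self.data.shape[2]

    @property
    def class_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            data=self.data,
            labels=self.labels,
            image_ids=self.image_ids,
            fs=np.asarray(self.fs),
            channel_names=np.asarray(self.channel_names, dtype=object),
        )

    @classmethod
    def load(cls, path) -> "EpochSet":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                data=z["data"],
                labels=z["labels"],
                image_ids=z["image_ids"],
                fs=float(z["fs"]),
                channel_names=list(z["channel_names"]),
            )


@dataclass
class ContinuousRecording:
    """Unsegmented multichannel EEG with an event list.

    ``events`` is an (n_events, 2) int array of (sample index, label).
    """

    signal: np.ndarray
    fs: float
    channel_names: list = field(default_factory=list)
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.events = np.asarray(self.events, dtype=int).reshape(-1, 2)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be channel x sample")
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.events.size and (
            self.events[:, 0].min() < 0
            or self.events[:, 0].max() >= self.signal.shape[1]
        ):
            raise ValidationError("event sample indices must lie within the signal")
        if not self.channel_names:
            self.channel_names = [f"E{i + 1}" for i in range(self.signal.shape[0])]


def read_edf(path) -> ContinuousRecording:
    """Read an EDF/EDF+ file into a :class:`ContinuousRecording`.

    All channels are loaded at their native sampling rate; EDF+ annotations
    are mapped to events at ``round(onset * fs)``.  Annotation descriptions
    that parse as integers become the event labels directly; otherwise
    labels are assigned by the sorted order of the distinct descriptions
    (1-based).  A file without annotations yields an empty event list and a
    warning.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise EDFParseError(f"cannot parse EDF file {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    signal = raw.get_data() * 1e6  # mne returns volts; we work in microvolts
    ann = raw.annotations
    if len(ann) == 0:
        warnings.warn(f"no annotations found in {path}; event list is empty")
        events = np.empty((0, 2), dtype=int)
    else:
        descs = list(ann.description)
        try:
            labels = [int(d) for d in descs]
        except ValueError:
            mapping = {d: i + 1 for i, d in enumerate(sorted(set(descs)))}
            labels = [mapping[d] for d in descs]
        samples = np.round(np.asarray(ann.onset) * fs).astype(int)
        events = np.column_stack([samples, labels])
    return ContinuousRecording(
        signal=signal, fs=fs, channel_names=list(raw.ch_names), events=events
    )


def bandpass_filter(rec: ContinuousRecording, lo: float, hi: float) -> ContinuousRecording:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward).

    The band must satisfy ``0 < lo < hi < fs/2``.  Signal length and the
    event list are preserved.
    """
    nyq = rec.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValidationError(
            f"band must satisfy 0 < lo < hi < fs/2 (got lo={lo}, hi={hi}, fs={rec.fs})"
        )
    sos = butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, rec.signal, axis=1)
    return replace(rec, signal=filtered)


def epoch_extract(rec: ContinuousRecording, window_s: float) -> EpochSet:
    """Cut one trial per event.

    Windows are half-open ``[onset, onset + round(window_s * fs))`` with
    0-based sample indexing; the label comes from the event.  Events whose
    window overruns the recording raise, listing the offenders.
    """
    if rec.events.size == 0:
        raise ValidationError("recording has no events to epoch")
    win = int(round(window_s * rec.fs))
    if win < 1:
        raise ValidationError(f"window {window_s}s too short at fs={rec.fs}")
    n = rec.signal.shape[1]
    bad = [int(s) for s, _ in rec.events if s + win > n]
    if bad:
        raise ValidationError(
            f"{len(bad)} event(s) too close to the recording end (onsets {bad}); "
            f"window needs {win} samples"
        )
    trials = np.stack([rec.signal[:, s : s + win] for s, _ in rec.events])
    labels = rec.events[:, 1]
    return EpochSet(
        data=trials,
        labels=labels,
        image_ids=np.arange(len(labels)),
        fs=rec.fs,
        channel_names=list(rec.channel_names),
    )
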