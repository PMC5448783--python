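"""Synthetic multichannel EEG with controllable class separability.

The generator emulates a visual object-category study: K balanced classes
of stimuli, each image presented a fixed number of times, 1-s epochs at
250 Hz over a dense electrode array.  Each trial is a class-dependent
evoked waveform (a Gaussian-windowed half-sine bump at a class-specific
latency, restricted to a subset of channels) buried in a mixture of 1/f
("pink") and white noise.  Setting every template amplitude to zero gives
exchangeable classes — the null model used for chance-level calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .epochs import EpochSet, ValidationError


@dataclass
class EvokedTemplate:
    """One class's evoked response: a Gaussian-windowed half-sine bump.

    The bump spans ``[latency - width, latency + width]`` seconds, peaks at
    ``latency`` with value ``amplitude`` (microvolts), and is applied to
    the listed channels only.
    """

    amplitude: float
    latency: float
    width: float
    channels: tuple = ()

    def waveform(self, t: np.ndarray) -> np.ndarray:
        u = t - self.latency
        env = np.exp(-0.5 * (u / (self.width / 2.0)) ** 2)
        carrier = np.cos(np.pi * u / (2.0 * self.width))
        wave = self.amplitude * env * carrier
        wave[np.abs(u) > self.width] = 0.0
        return wave


@dataclass
class SyntheticSpec:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated design: 5 classes x 52 images x 2
    presentations, 128 channels, 1-s epochs at 250 Hz.
    """

    n_classes: int = 5
    images_per_class: int = 52
    presentations_per_image: int = 2
    n_channels: int = 128
    fs: float = 250.0
    epoch_len_s: float = 1.0
    evoked_templates: list = None
    noise_sd: float = 10.0
    pink_noise_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("n_classes", "images_per_class", "presentations_per_image", "n_channels"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        n_samp = self.fs * self.epoch_len_s
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValidationError(
                f"epoch_len_s * fs must be an integer (got {n_samp})"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0.0 <= self.pink_noise_fraction <= 1.0):
            raise ValidationError(
                f"pink_noise_fraction must lie in [0, 1], got {self.pink_noise_fraction}"
            )
        if self.evoked_templates is None:
            self.evoked_templates = default_templates(self.n_classes, self.n_channels)
        if len(self.evoked_templates) != self.n_classes:
            raise ValidationError("evoked_templates must have one entry per class")
        self.evoked_templates = [
            t if isinstance(t, EvokedTemplate) else EvokedTemplate(**t)
            for t in self.evoked_templates
        ]
        for k, t in enumerate(self.evoked_templates):
            for c in t.channels:
                if not (0 <= c < self.n_channels):
                    raise ValidationError(
                        f"evoked_templates[{k}]: channel {c} >= n_channels={self.n_channels}"
                    )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len_s))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["evoked_templates"] = [
            {**asdict(t), "channels": list(t.channels)} for t in self.evoked_templates
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if d.get("evoked_templates") is not None:
            d["evoked_templates"] = [
                EvokedTemplate(
                    amplitude=t["amplitude"],
                    latency=t["latency"],
                    width=t["width"],
                    channels=tuple(t.get("channels", ())),
                )
                for t in d["evoked_templates"]
            ]
        return cls(**d)


def default_templates(n_classes: int, n_channels: int) -> list:
    """Class templates: same posterior channel subset, staggered latencies.

    Amplitude 5 uV, width 50 ms, latencies 100 ms apart starting at 120 ms
    — an ERP-like difference that is detectable but not trivial at the
    default noise level.
    """
    n_aff = max(1, n_channels // 4)
    channels = tuple(range(n_aff))
    return [
        EvokedTemplate(amplitude=5.0, latency=0.12 + 0.1 * k, width=0.05, channels=channels)
        for k in range(n_classes)
    ]


def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    n_freq = n_samples // 2 + 1
    freqs = np.arange(n_freq, dtype=float)
    amp = np.zeros(n_freq)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])  # 1/f power  =>  1/sqrt(f) amplitude
    phases = rng.uniform(0, 2 * np.pi, size=shape + (n_freq,))
    spec = amp * np.exp(1j * phases)
    spec[..., 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_epochs(spec: SyntheticSpec) -> EpochSet:
    """Draw a full synthetic data set.

    Returns ``n_classes * images_per_class * presentations_per_image``
    trials of shape (n_channels, n_samples), labels balanced, trials
    ordered class-major then image then presentation.  Identical specs
    (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_trials = spec.n_classes * spec.images_per_class * spec.presentations_per_image
    n_ch, n_samp = spec.n_channels, spec.n_samples
    t = np.arange(n_samp) / spec.fs

    signal = np.zeros((spec.n_classes, n_ch, n_samp))
    for k, tmpl in enumerate(spec.evoked_templates):
        if tmpl.channels:
            signal[k, list(tmpl.channels), :] = tmpl.waveform(t)

    data = np.empty((n_trials, n_ch, n_samp))
    labels = np.empty(n_trials, dtype=int)
    image_ids = np.empty(n_trials, dtype=int)

    frac = spec.pink_noise_fraction
    w_pink, w_white = np.sqrt(frac), np.sqrt(1.0 - frac)

    i = 0
    for k in range(spec.n_classes):
        for img in range(spec.images_per_class):
            image_id = k * spec.images_per_class + img
            for _ in range(spec.presentations_per_image):
                noise = w_white * rng.standard_normal((n_ch, n_samp))
                if frac > 0:
                    noise = noise + w_pink * _pink_noise(rng, (n_ch,), n_samp)
                data[i] = signal[k] + spec.noise_sd * noise
                labels[i] = k + 1
                image_ids[i] = image_id
                i += 1

    return EpochSet(data=data, labels=labels, image_ids=image_ids, fs=spec.fs)


def average_presentations(epochs: EpochSet) -> EpochSet:
    """Average repeated presentations of each image into one trial.

    Every image id must appear the same number of times; labels are
    preserved (presentations of one image always share a class).
    """
    ids, counts = np.unique(epochs.image_ids, return_counts=True)
    if len(set(counts)) > 1:
        bad = ids[counts != counts[0]]
        raise ValidationError(
            f"unbalanced presentation counts for image ids {bad.tolist()}"
        )
    data = np.empty((len(ids), epochs.n_channels, epochs.n_samples))
    labels = np.empty(len(ids), dtype=int)
    for j, img in enumerate(ids):
        mask = epochs.image_ids == img
        data[j] = epochs.data[mask].mean(axis=0)
        lab = np.unique(epochs.labels[mask])
        if len(lab) != 1:
            raise ValidationError(f"image id {img} appears under multiple labels")
        labels[j] = lab[0]
    return EpochSet(
        data=data,
        labels=labels,
        image_ids=ids,
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
    )
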