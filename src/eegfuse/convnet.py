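"""Random-kernel 1-D convolutional feature extraction.

Each channel row of a trial is passed through a bank of M shared 1-D
filters (valid, no-padding cross-correlation), a pointwise nonlinearity,
and non-overlapping pooling.  The pooled maps are concatenated — channel
major, then map, then pooled position — into one feature vector per trial.
The kernels are drawn i.i.d. Gaussian and are *not* trained: the bank acts
as a fixed random projection that expands each row into many band-limited
views, and discrimination is deferred to feature selection and the
classifier downstream.

With the default geometry (250-sample rows, filter length 130, pool width
11, 100 maps) each row yields (250-130+1) = 121 map samples, pooled into
121 // 11 = 11 positions, i.e. 100 x 11 = 1100 features per channel row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .epochs import EpochSet, ValidationError

_ACTIVATIONS = ("sigmoid", "tanh", "identity")
_POOLING = ("mean", "max")


@dataclass
class ConvNetSpec:
    """Architecture and parameters of the feature extractor.

    ``activation="identity"`` is a test hook (no squashing); the study
    configurations are sigmoid (default) or tanh.
    """

    n_maps: int = 100
    filter_len: int = 130
    pool_width: int = 11
    activation: str = "sigmoid"
    pooling_mode: str = "mean"
    init_sd: float = 1.0
    seed: int = 0
    weights: np.ndarray = None
    biases: np.ndarray = None

    def __post_init__(self):
        if self.n_maps < 1:
            raise ValidationError(f"n_maps must be >= 1, got {self.n_maps}")
        if self.filter_len < 1:
            raise ValidationError(f"filter_len must be >= 1, got {self.filter_len}")
        if self.pool_width < 1:
            raise ValidationError(f"pool_width must be >= 1, got {self.pool_width}")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"activation must be one of {_ACTIVATIONS}")
        if self.pooling_mode not in _POOLING:
            raise ValidationError(f"pooling_mode must be one of {_POOLING}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_maps, self.filter_len):
                raise ValidationError("weights must have shape (n_maps, filter_len)")
        if self.biases is not None:
            self.biases = np.asarray(self.biases, dtype=float)
            if self.biases.shape != (self.n_maps,):
                raise ValidationError("biases must have shape (n_maps,)")

    def n_features_per_row(self, n_samples: int) -> int:
        l_out = n_samples - self.filter_len + 1
        if l_out < self.pool_width:
            raise ValidationError(
                f"geometry infeasible: n_samples={n_samples}, "
                f"filter_len={self.filter_len}, pool_width={self.pool_width}"
            )
        return self.n_maps * (l_out // self.pool_width)

    def to_json(self, path) -> None:
        d = {
            "n_maps": self.n_maps,
            "filter_len": self.filter_len,
            "pool_width": self.pool_width,
            "activation": self.activation,
            "pooling_mode": self.pooling_mode,
            "init_sd": self.init_sd,
            "seed": self.seed,
            "weights": None if self.weights is None else self.weights.tolist(),
            "biases": None if self.biases is None else self.biases.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "ConvNetSpec":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("weights") is not None:
            d["weights"] = np.asarray(d["weights"])
        if d.get("biases") is not None:
            d["biases"] = np.asarray(d["biases"])
        return cls(**d)


@dataclass
class FeatureMatrix:
    """Trials x features, with per-feature provenance.

    ``provenance`` maps each feature column back to (channel index, map
    index, pooled position) — for wavelet features the map index is the
    decomposition level, for raw features channel/sample.  ``method_tag``
    is one of {"convnet", "wavelet", "raw"}.
    """

    values: np.ndarray
    provenance: np.ndarray  # (n_features, 3) int: channel, map/level, position
    method_tag: str = "convnet"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=int).reshape(-1, 3)
        if self.values.ndim != 2:
            raise ValidationError("values must be trials x features")
        if self.provenance.shape[0] != self.values.shape[1]:
            raise ValidationError("provenance length must equal n_features")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            values=self.values,
            provenance=self.provenance,
            method_tag=np.asarray(self.method_tag),
        )

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                values=z["values"],
                provenance=z["provenance"],
                method_tag=str(z["method_tag"]),
            )


def init_filters(spec: ConvNetSpec) -> ConvNetSpec:
    """Draw the filter bank: W ~ i.i.d. N(0, init_sd^2), biases zero.

    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    w = rng.normal(0.0, spec.init_sd, size=(spec.n_maps, spec.filter_len))
    b = np.zeros(spec.n_maps)
    return replace(spec, weights=w, biases=b)


def activate(sigma, mode: str = "sigmoid"):
    """Pointwise nonlinearity: logistic sigmoid (default), tanh, or identity."""
    sigma = np.asarray(sigma, dtype=float)
    if mode == "sigmoid":
        # expit form, saturates cleanly at the extremes
        out = np.empty_like(sigma)
        pos = sigma >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-sigma[pos]))
        e = np.exp(sigma[~pos])
        out[~pos] = e / (1.0 + e)
        return out if out.ndim else float(out)
    if mode == "tanh":
        return np.tanh(sigma)
    if mode == "identity":
        return sigma
    raise ValidationError(f"unknown activation {mode!r}")


def conv_forward(row: np.ndarray, spec: ConvNetSpec) -> np.ndarray:
    """Valid cross-correlation of one row with every filter, then activate.

    Returns an (n_maps, L_out) map matrix with L_out = N_s - filter_len + 1.
    """
    row = np.asarray(row, dtype=float).ravel()
    if spec.weights is None or spec.biases is None:
        raise ValidationError("filters not initialized; call init_filters first")
    if row.size < spec.filter_len:
        raise ValidationError(
            f"row length {row.size} shorter than filter_len {spec.filter_len}"
        )
    windows = sliding_window_view(row, spec.filter_len)  # (L_out, filter_len)
    sigma = windows @ spec.weights.T + spec.biases  # (L_out, n_maps)
    return activate(sigma, spec.activation).T


def pool_maps(maps: np.ndarray, pool_width: int, pooling_mode: str = "mean") -> np.ndarray:
    """Non-overlapping pooling of each map; trailing remainder discarded."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2:
        raise ValidationError("maps must be 2-D (n_maps x L_out)")
    l_out = maps.shape[1]
    if pool_width > l_out:
        raise ValidationError(f"pool_width {pool_width} exceeds map length {l_out}")
    n_pool = l_out // pool_width
    blocks = maps[:, : n_pool * pool_width].reshape(maps.shape[0], n_pool, pool_width)
    if pooling_mode == "mean":
        return blocks.mean(axis=2)
    if pooling_mode == "max":
        return blocks.max(axis=2)
    raise ValidationError(f"unknown pooling mode {pooling_mode!r}")


def extract_convnet_features(
    epochs: EpochSet, spec: ConvNetSpec, chunk: int = 256
) -> FeatureMatrix:
    """Apply the extractor to every channel row of every trial.

    Per row: conv_forward then pool_maps, flattened map-major; channels are
    concatenated.  The same (seeded) filter bank is shared by all channels
    and trials, so rows are processed independently and trial order is
    immaterial.  ``chunk`` bounds how many rows are convolved at once to
    cap peak memory.
    """
    if spec.weights is None:
        spec = init_filters(spec)
    n_t, n_ch, n_s = epochs.n_trials, epochs.n_channels, epochs.n_samples
    if n_s < spec.filter_len:
        raise ValidationError(
            f"geometry infeasible: N_s={n_s} < filter_len={spec.filter_len}"
        )
    l_out = n_s - spec.filter_len + 1
    if l_out < spec.pool_width:
        raise ValidationError(
            f"geometry infeasible: N_s={n_s}, filter_len={spec.filter_len}, "
            f"pool_width={spec.pool_width}"
        )
    n_pool = l_out // spec.pool_width
    per_row = spec.n_maps * n_pool

    rows = epochs.data.reshape(n_t * n_ch, n_s)
    out = np.empty((n_t * n_ch, spec.n_maps, n_pool))
    for start in range(0, rows.shape[0], chunk):
        block = rows[start : start + chunk]
        windows = sliding_window_view(block, spec.filter_len, axis=1)
        # windows: (rows, L_out, filter_len)
        sigma = windows @ spec.weights.T + spec.biases  # (rows, L_out, n_maps)
        acts = activate(sigma, spec.activation)
        trimmed = acts[:, : n_pool * spec.pool_width, :]
        blocks = trimmed.reshape(block.shape[0], n_pool, spec.pool_width, spec.n_maps)
        pooled = blocks.mean(axis=2) if spec.pooling_mode == "mean" else blocks.max(axis=2)
        out[start : start + chunk] = pooled.transpose(0, 2, 1)  # map-major

    values = out.reshape(n_t, n_ch * per_row)
    ch_idx = np.repeat(np.arange(n_ch), per_row)
    map_idx = np.tile(np.repeat(np.arange(spec.n_maps), n_pool), n_ch)
    pos_idx = np.tile(np.arange(n_pool), n_ch * spec.n_maps)
    provenance = np.column_stack([ch_idx, map_idx, pos_idx])
    return FeatureMatrix(values=values, provenance=provenance, method_tag="convnet")


def extract_raw_features(epochs: EpochSet) -> FeatureMatrix:
    """Baseline: flatten each trial (channel-major) into a feature vector."""
    n_t, n_ch, n_s = epochs.n_trials, epochs.n_channels, epochs.n_samples
    values = epochs.data.reshape(n_t, n_ch * n_s)
    provenance = np.column_stack(
        [np.repeat(np.arange(n_ch), n_s), np.zeros(n_ch * n_s, dtype=int),
         np.tile(np.arange(n_s), n_ch)]
    )
    return FeatureMatrix(values=values, provenance=provenance, method_tag="raw")
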