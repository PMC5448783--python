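"""Discrete-wavelet-transform baseline features.

Each channel row is decomposed with a multilevel DWT (PyWavelets); the
approximation coefficients plus every detail level are concatenated across
channels into the feature vector.  Default: db4, maximum feasible level,
zero-padding boundary.
"""

from __future__ import annotations

import numpy as np
import pywt

from .convnet import FeatureMatrix
from .epochs import EpochSet, ValidationError


def max_feasible_level(n_samples: int, wavelet_name: str) -> int:
    return pywt.dwt_max_level(n_samples, pywt.Wavelet(wavelet_name).dec_len)


def extract_wavelet_features(
    epochs: EpochSet,
    wavelet_name: str = "db4",
    n_levels: int = None,
    mode: str = "zero",
) -> FeatureMatrix:
    """Full multilevel DWT coefficient vector per channel row.

    Provenance records (channel, level, position) where level 0 is the
    coarsest approximation band and levels 1..n are details from coarse to
    fine.  ``n_levels`` defaults to the maximum feasible for the row
    length and wavelet; an infeasible request raises and states the
    maximum.
    """
    wavelet = pywt.Wavelet(wavelet_name)
    feasible = pywt.dwt_max_level(epochs.n_samples, wavelet.dec_len)
    if n_levels is None:
        n_levels = feasible
    if n_levels < 1 or n_levels > feasible:
        raise ValidationError(
            f"n_levels={n_levels} infeasible for N_s={epochs.n_samples} and "
            f"{wavelet_name} (maximum level {feasible})"
        )

    n_t, n_ch = epochs.n_trials, epochs.n_channels
    rows = epochs.data.reshape(n_t * n_ch, epochs.n_samples)
    coeffs = pywt.wavedec(rows, wavelet, level=n_levels, mode=mode, axis=1)
    per_row = np.concatenate(coeffs, axis=1)  # (rows, n_coeffs)
    n_coeff = per_row.shape[1]

    level_idx = np.concatenate(
        [np.full(c.shape[1], lev, dtype=int) for lev, c in enumerate(coeffs)]
    )
    pos_idx = np.concatenate([np.arange(c.shape[1]) for c in coeffs])
    values = per_row.reshape(n_t, n_ch * n_coeff)
    provenance = np.column_stack(
        [np.repeat(np.arange(n_ch), n_coeff), np.tile(level_idx, n_ch),
         np.tile(pos_idx, n_ch)]
    )
    return FeatureMatrix(values=values, provenance=provenance, method_tag="wavelet")
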