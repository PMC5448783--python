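"""Welch t-test feature ranking and nested subset construction.

Features are scored per class pair with a two-sample Welch t statistic

    t(j) = (mean_A(j) - mean_B(j)) / sqrt(var_A(j)/|A| + var_B(j)/|B|)

with Welch-Satterthwaite degrees of freedom and a two-sided p value.
Features with p >= alpha (default 0.05) are excluded; the survivors are
ranked ascending by p (ties: |t| descending, then feature index).  Nested
subsets — the top 50, 100, ..., 5000 by default — feed the
accuracy-versus-feature-count sweep.  Ranking must be computed on training
trials only; it never sees test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .convnet import FeatureMatrix
from .epochs import ValidationError


@dataclass
class SelectionResult:
    """Per-feature t/p values plus the significant-feature ranking."""

    t_values: np.ndarray
    p_values: np.ndarray
    ranked_indices: np.ndarray
    alpha: float
    class_pair: tuple
    degenerate: np.ndarray = None  # zero spread in both groups, unequal means
    subset_sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_significant(self) -> int:
        return len(self.ranked_indices)

    def top(self, n: int) -> np.ndarray:
        """Indices of the top-n features (truncated to what is available)."""
        return self.ranked_indices[: min(n, len(self.ranked_indices))]

    def to_frame(self, provenance: np.ndarray = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": np.arange(len(self.t_values)),
                "t": self.t_values,
                "p": self.p_values,
            }
        )
        if provenance is not None:
            df["channel"] = provenance[:, 0]
            df["map"] = provenance[:, 1]
            df["position"] = provenance[:, 2]
        rank = np.full(len(self.t_values), -1)
        rank[self.ranked_indices] = np.arange(len(self.ranked_indices))
        df["rank"] = rank
        return df


def welch_t(xA, xB):
    """Welch two-sample t statistic and two-sided p for one feature.

    Degenerate cases: identical constant groups give (0, 1); zero spread
    in both groups with unequal means gives (+-inf, 0) — maximally
    significant, flagged upstream.
    """
    xA = np.asarray(xA, dtype=float)
    xB = np.asarray(xB, dtype=float)
    if len(xA) < 2 or len(xB) < 2:
        raise ValidationError("welch_t needs at least 2 values per group")
    t, p, _ = _welch_arrays(xA[:, None], xB[:, None])
    return float(t[0]), float(p[0])


def _welch_arrays(a, b):
    """Vectorized Welch t over feature columns; returns (t, p, degenerate)."""
    nA, nB = a.shape[0], b.shape[0]
    mA, mB = a.mean(axis=0), b.mean(axis=0)
    vA, vB = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = vA / nA + vB / nB
    diff = mA - mB
    degenerate = (se2 == 0) & (diff != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1))
    # both groups constant and equal: define t=0, p=1
    both_const_eq = (se2 == 0) & (diff == 0)
    t[both_const_eq] = 0.0
    df[se2 == 0] = 1.0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[both_const_eq] = 1.0
    p[degenerate] = 0.0
    t[degenerate] = np.where(diff[degenerate] > 0, np.inf, -np.inf)
    return t, p, degenerate


def rank_features(
    features, labels, class_pair: tuple, alpha: float = 0.05
) -> SelectionResult:
    """Rank every feature by the Welch test between two classes.

    ``features`` is a FeatureMatrix or a (trials, features) array aligned
    with ``labels``.  Only trials of the two classes are used.
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    a_id, b_id = class_pair
    a = values[labels == a_id]
    b = values[labels == b_id]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"both classes of pair {class_pair} need >= 2 trials "
            f"(got {len(a)}, {len(b)})"
        )
    t, p, degenerate = _welch_arrays(a, b)
    order = np.lexsort((np.arange(len(p)), -np.abs(t), p))
    ranked = order[p[order] < alpha]
    return SelectionResult(
        t_values=t,
        p_values=p,
        ranked_indices=ranked,
        alpha=alpha,
        class_pair=(a_id, b_id),
        degenerate=degenerate,
    )


def subset_sizes(start: int = 50, stop: int = 5000, step: int = 50) -> np.ndarray:
    """Arithmetic subset-size ladder, inclusive of aligned endpoints.

    Defaults give the 100-level ladder 50, 100, ..., 5000.
    """
    if start < 1 or step < 1 or stop < start:
        raise ValidationError(
            f"need start >= 1, step >= 1, stop >= start (got {start}, {stop}, {step})"
        )
    return np.arange(start, stop + 1, step)


def union_top_n(rankings: dict, n: int) -> np.ndarray:
    """Union of the top-n features over per-pair rankings (multiclass).

    ``rankings`` maps a class pair to its SelectionResult.  Returned
    indices are sorted ascending for deterministic downstream order.
    """
    sel = set()
    for res in rankings.values():
        sel.update(res.top(n).tolist())
    return np.array(sorted(sel), dtype=int)
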