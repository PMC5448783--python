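"""Likelihood-ratio-based score fusion (LRBSF).

The classifier models each class by per-feature Gaussian kernel density
estimates fitted on training trials only, and fuses the per-feature
evidence by summing log marginal densities (class-conditional
independence).  A test vector x gets, for class c with selected features
j = 1..p,

    S_c(x) = sum_j log f_hat_{c,j}(x_j)

Two-class decisions use the log likelihood ratio S_1 - S_0 against a
threshold log(eta) (default eta = 1, the Neyman-Pearson boundary point;
the boundary itself is assigned to the alternative class M1).  Multiclass
decisions take the argmax of the S_c, ties to the smallest class id.

Bandwidths follow Silverman's rule of thumb per feature per class,
h = 0.9 * min(sd, IQR/1.34) * n^(-1/5).  Densities are floored at a tiny
eps before the log so far-out test points yield large-but-finite
penalties rather than -inf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .epochs import ValidationError

DENSITY_FLOOR = 1e-300
_LOG_FLOOR = np.log(DENSITY_FLOOR)


def silverman_bandwidth(values: np.ndarray, fallback_scale: float = 1.0) -> float:
    """Silverman rule-of-thumb bandwidth for a 1-D sample.

    Zero-spread candidates are dropped; a fully degenerate sample (no
    positive spread at all) falls back to ``1e-6 * fallback_scale`` so the
    density stays proper.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need >= 2 training values to fit a KDE")
    sd = v.std(ddof=1)
    q75, q25 = np.percentile(v, [75, 25])
    iqr_scale = (q75 - q25) / 1.34
    candidates = [s for s in (sd, iqr_scale) if s > 0]
    if not candidates:
        return 1e-6 * max(abs(fallback_scale), 1e-12)
    return 0.9 * min(candidates) * v.size ** (-0.2)


@dataclass
class FeatureDensity:
    """Gaussian KDE for one feature of one class."""

    train: np.ndarray
    bandwidth: float

    def logpdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.train[None, :]) / self.bandwidth
        lp = logsumexp(-0.5 * z**2, axis=1) - np.log(
            self.train.size * self.bandwidth * np.sqrt(2 * np.pi)
        )
        return np.maximum(lp, _LOG_FLOOR)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))


def fit_kde(values, fallback_scale: float = 1.0) -> FeatureDensity:
    """Fit a single-feature Gaussian KDE with Silverman bandwidth."""
    v = np.asarray(values, dtype=float)
    h = silverman_bandwidth(v, fallback_scale=fallback_scale)
    return FeatureDensity(train=v, bandwidth=h)


@dataclass
class ClassDensityModel:
    """Per-feature KDEs for one class over a fixed selected-feature set."""

    class_id: int
    feature_ids: np.ndarray
    train: np.ndarray       # (n_train, n_features)
    bandwidths: np.ndarray  # (n_features,)

    @classmethod
    def fit(
        cls, X: np.ndarray, class_id: int, feature_ids=None, global_scale=None
    ) -> "ClassDensityModel":
        """Fit from training trials (rows) of the selected features (cols).

        ``global_scale`` supplies the per-feature fallback scale used when
        a feature has zero spread within this class (typically the pooled
        spread across classes).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("need a 2-D (n_train >= 2, n_features) matrix")
        n_feat = X.shape[1]
        if feature_ids is None:
            feature_ids = np.arange(n_feat)
        feature_ids = np.asarray(feature_ids, dtype=int)
        if global_scale is None:
            global_scale = X.std(axis=0, ddof=1)
        global_scale = np.broadcast_to(np.asarray(global_scale, dtype=float), (n_feat,))
        # vectorized Silverman rule (same semantics as silverman_bandwidth)
        sd = X.std(axis=0, ddof=1)
        q75, q25 = np.percentile(X, [75, 25], axis=0)
        iqr_scale = (q75 - q25) / 1.34
        cand = np.minimum(
            np.where(sd > 0, sd, np.inf), np.where(iqr_scale > 0, iqr_scale, np.inf)
        )
        bw = 0.9 * cand * X.shape[0] ** (-0.2)
        fallback = 1e-6 * np.maximum(np.abs(global_scale), 1e-12)
        bw = np.where(np.isfinite(bw), bw, fallback)
        return cls(class_id=class_id, feature_ids=feature_ids, train=X.copy(), bandwidths=bw)

    def log_marginals(self, X: np.ndarray) -> np.ndarray:
        """Floored log f_hat_{c,j}(x_j) for each trial and feature.

        Returns (n_trials, n_features).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.train.shape[1]:
            raise ValidationError(
                f"feature-set mismatch: model has {self.train.shape[1]} features, "
                f"input has {X.shape[1]}"
            )
        # (n_trials, n_train, n_features)
        z = (X[:, None, :] - self.train[None, :, :]) / self.bandwidths[None, None, :]
        lp = logsumexp(-0.5 * z**2, axis=1) - np.log(
            self.train.shape[0] * self.bandwidths * np.sqrt(2 * np.pi)
        )
        return np.maximum(lp, _LOG_FLOOR)

    def log_score(self, X: np.ndarray) -> np.ndarray:
        """Summed log marginal density per trial: S_c(x)."""
        return self.log_marginals(X).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "class_id": int(self.class_id),
            "feature_ids": self.feature_ids.tolist(),
            "train": self.train.tolist(),
            "bandwidths": self.bandwidths.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassDensityModel":
        return cls(
            class_id=d["class_id"],
            feature_ids=np.asarray(d["feature_ids"], dtype=int),
            train=np.asarray(d["train"], dtype=float),
            bandwidths=np.asarray(d["bandwidths"], dtype=float),
        )


@dataclass
class DecisionRule:
    """Two-class LRT decision parameters.

    ``eta`` is the likelihood-ratio threshold (decide M1 iff LR >= eta);
    ``alpha`` records the nominal test level but is unused by default —
    the threshold is eta, found from training accuracy when requested.
    ``class_map`` is (M0 class id, M1 class id).
    """

    eta: float = 1.0
    alpha: float = 0.05
    class_map: tuple = (0, 1)

    def __post_init__(self):
        if self.eta <= 0:
            raise ValidationError(f"eta must be > 0, got {self.eta}")


def _check_same_features(model1: ClassDensityModel, model0: ClassDensityModel):
    if not np.array_equal(model1.feature_ids, model0.feature_ids):
        raise ValidationError("models were fitted on different selected-feature sets")


def loglr(x, model1: ClassDensityModel, model0: ClassDensityModel):
    """Log likelihood ratio log f1(x) - log f0(x), summed over features."""
    _check_same_features(model1, model0)
    s1 = model1.log_score(x)
    s0 = model0.log_score(x)
    out = s1 - s0
    return float(out[0]) if out.size == 1 and np.ndim(x) == 1 else out


def decide_pairwise(loglr_value: float, rule: DecisionRule):
    """Assign M1 iff log LR >= log eta (boundary goes to M1), else M0."""
    m0, m1 = rule.class_map
    return m1 if loglr_value >= np.log(rule.eta) else m0


def select_eta(scores, labels, m1_class) -> float:
    """Threshold maximizing training accuracy.

    Candidates are the midpoints between sorted distinct log-LR scores
    plus log(1) = 0; ties are broken toward eta closest to 1.  Returns eta
    on the ratio (not log) scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_m1 = labels == m1_class
    if is_m1.all() or (~is_m1).all():
        raise ValidationError("select_eta needs both classes present")
    distinct = np.unique(scores)
    cands = [0.0]
    if len(distinct) > 1:
        cands.extend(((distinct[:-1] + distinct[1:]) / 2.0).tolist())
    cands = np.asarray(cands)
    acc = np.array([np.mean((scores >= c) == is_m1) for c in cands])
    best = acc == acc.max()
    log_eta = cands[best][np.argmin(np.abs(cands[best]))]
    return float(np.exp(log_eta))


def class_scores(x, models: list) -> np.ndarray:
    """Fused score S_k per class model; models must share feature sets."""
    ref = models[0]
    for m in models[1:]:
        _check_same_features(m, ref)
    cols = [m.log_score(x) for m in models]
    out = np.column_stack(cols)
    return out[0] if np.ndim(x) == 1 else out


def decide_multiclass(scores, class_ids=None):
    """Argmax over class scores; ties go to the smallest class id.

    ``scores`` is (K,) or (n, K); ``class_ids`` defaults to 1..K.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    k = scores.shape[1]
    if k < 2:
        raise ValidationError("need K >= 2 class scores")
    if class_ids is None:
        class_ids = np.arange(1, k + 1)
    class_ids = np.asarray(class_ids)
    order = np.argsort(class_ids)  # argmax's first-hit rule then favors small ids
    idx = order[np.argmax(scores[:, order], axis=1)]
    out = class_ids[idx]
    return out if scores.shape[0] > 1 else out[0]


class LRBSFClassifier:
    """sklearn-style wrapper: fit per-class KDE models, predict by fusion.

    For K = 2 the decision is the pairwise LRT with threshold ``eta``
    (optionally tuned on training scores); for K > 2 it is the argmax
    fusion rule, where ``eta`` plays no role.
    """

    def __init__(self, eta: float = 1.0, tune_eta: bool = False):
        self.eta = eta
        self.tune_eta = tune_eta
        self.models_ = None
        self.class_ids_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.class_ids_ = np.unique(y)
        pooled_scale = X.std(axis=0, ddof=1)
        self.models_ = [
            ClassDensityModel.fit(X[y == c], class_id=int(c), global_scale=pooled_scale)
            for c in self.class_ids_
        ]
        if len(self.class_ids_) == 2 and self.tune_eta:
            scores = self._pair_scores(X)
            self.eta = select_eta(scores, y, m1_class=self.class_ids_[0])
        return self

    def _pair_scores(self, X):
        # M1 = smaller class id (pair orientation: first class is positive)
        m1, m0 = self.models_[0], self.models_[1]
        return loglr(np.atleast_2d(X), m1, m0)

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(self.class_ids_) == 2:
            rule = DecisionRule(
                eta=self.eta, class_map=(int(self.class_ids_[1]), int(self.class_ids_[0]))
            )
            s = self._pair_scores(X)
            return np.array([decide_pairwise(v, rule) for v in s])
        s = class_scores(X, self.models_)
        return np.asarray(decide_multiclass(s, class_ids=self.class_ids_)).reshape(-1)

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "eta": self.eta,
                    "tune_eta": self.tune_eta,
                    "class_ids": self.class_ids_.tolist(),
                    "models": [m.to_dict() for m in self.models_],
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "LRBSFClassifier":
        with open(path) as fh:
            d = json.load(fh)
        obj = cls(eta=d["eta"], tune_eta=d["tune_eta"])
        obj.class_ids_ = np.asarray(d["class_ids"], dtype=int)
        obj.models_ = [ClassDensityModel.from_dict(m) for m in d["models"]]
        return obj
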