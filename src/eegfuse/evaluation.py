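"""Monte-Carlo cross-validation, chance levels and method comparison.

The evaluation protocol: repeat ``n_reps`` times (default 100) a
stratified random split into 90% training / 10% test; on the training
fold only, rank features by the Welch test and fit the classifier; score
the test fold into a confusion matrix.  Reported accuracy is the mean
over repetitions, per selected subset size.

Chance levels come in two flavors: the analytic (1 - alpha) quantile of
the binomial null accuracy distribution, and an empirical permutation
version — the same quantile of the accuracy of uniform random guessing
against balanced true labels over ``n_permutations`` draws (equivalent to
label permutation for an uninformative classifier, and far cheaper than
refitting; a refit variant is available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .convnet import FeatureMatrix
from .epochs import ValidationError
from .lrbsf import LRBSFClassifier
from .selection import rank_features, union_top_n


@dataclass
class CVReport:
    """Confusion matrices and summaries from one Monte-Carlo CV run.

    ``confusions`` has shape (n_reps, n_sizes, K, K); rows index the true
    class (ascending class id), columns the predicted class.
    """

    confusions: np.ndarray
    subset_sizes: np.ndarray
    class_ids: np.ndarray
    n_repetitions: int
    test_fraction: float
    seed: int
    method: str = "lrbsf"
    test_indices: list = field(default_factory=list)

    @property
    def accuracy_per_rep(self) -> np.ndarray:
        """(n_reps, n_sizes) accuracy in %."""
        tr = np.trace(self.confusions, axis1=2, axis2=3)
        tot = self.confusions.sum(axis=(2, 3))
        return 100.0 * tr / tot

    @property
    def accuracy_curve(self) -> np.ndarray:
        """Mean accuracy (%) per subset size."""
        return self.accuracy_per_rep.mean(axis=0)

    @property
    def headline_accuracy(self) -> float:
        """Maximum of the mean accuracy curve over subset sizes.

        Note this max-over-sizes convention is optimistically biased when
        many sizes are swept; single-size runs are unaffected.
        """
        return float(self.accuracy_curve.max())

    @property
    def best_size(self) -> int:
        return int(self.subset_sizes[int(np.argmax(self.accuracy_curve))])

    def mean_accuracy(self, size_index: int = 0) -> float:
        return float(self.accuracy_per_rep[:, size_index].mean())

    def accuracy_se(self, size_index: int = 0) -> float:
        a = self.accuracy_per_rep[:, size_index]
        return float(a.std(ddof=1) / np.sqrt(len(a)))

    def summary(self, size_index: int = None) -> dict:
        """Accuracy (and sensitivity/specificity for 2 classes) in %.

        Sensitivity/specificity are computed from the confusion summed
        over repetitions, with the first class of the pair as positive.
        """
        if size_index is None:
            size_index = int(np.argmax(self.accuracy_curve))
        agg = self.confusions[:, size_index].sum(axis=0)
        out = {
            "subset_size": int(self.subset_sizes[size_index]),
            "accuracy": float(100.0 * np.trace(agg) / agg.sum()),
            "accuracy_se": self.accuracy_se(size_index),
        }
        if len(self.class_ids) == 2:
            acc, sens, spec = confusion_stats(agg)
            out.update({"sensitivity": sens, "specificity": spec})
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "confusions": self.confusions.tolist(),
                    "subset_sizes": self.subset_sizes.tolist(),
                    "class_ids": self.class_ids.tolist(),
                    "n_repetitions": self.n_repetitions,
                    "test_fraction": self.test_fraction,
                    "seed": self.seed,
                    "method": self.method,
                    "test_indices": [list(map(int, t)) for t in self.test_indices],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "CVReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            confusions=np.asarray(d["confusions"], dtype=int),
            subset_sizes=np.asarray(d["subset_sizes"], dtype=int),
            class_ids=np.asarray(d["class_ids"], dtype=int),
            n_repetitions=d["n_repetitions"],
            test_fraction=d["test_fraction"],
            seed=d["seed"],
            method=d["method"],
            test_indices=[np.asarray(t, dtype=int) for t in d["test_indices"]],
        )


@dataclass
class ChanceLevel:
    """Empirical and analytic (1 - alpha) chance-accuracy thresholds (%)."""

    n_samples: int
    n_classes: int
    alpha: float
    n_permutations: int
    empirical_pct: float
    analytic_pct: float
    null_accuracies: np.ndarray = None


def mc_splits(labels, test_fraction: float, n_reps: int, seed: int):
    """Stratified random train/test splits, a pure function of its inputs.

    Per class the test count is floor(test_fraction * n_c); any remainder
    needed to reach round(test_fraction * n) is assigned round-robin in
    class-id order.  Yields (train_idx, test_idx) pairs.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if not (0 < test_fraction < 1):
        raise ValidationError(f"test_fraction must be in (0,1), got {test_fraction}")
    classes = np.unique(labels)
    counts = {c: int((labels == c).sum()) for c in classes}
    base = {c: int(np.floor(test_fraction * counts[c])) for c in classes}
    total = max(1, int(round(test_fraction * n)))
    rem = total - sum(base.values())
    i = 0
    while rem > 0 and i < 2 * len(classes) * (total + 1):
        c = classes[i % len(classes)]
        if base[c] + 1 < counts[c]:
            base[c] += 1
            rem -= 1
        i += 1
    for c in classes:
        if counts[c] - base[c] < 2:
            raise ValidationError(
                f"class {c} has too few trials ({counts[c]}) for "
                f"test_fraction={test_fraction}"
            )
        if base[c] < 1:
            base[c] = 1  # keep every class represented in the test fold
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        test = []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            perm = rng.permutation(idx)
            test.append(perm[: base[c]])
        test = np.sort(np.concatenate(test))
        train = np.setdiff1d(np.arange(n), test)
        out.append((train, test))
    return out


def _fit_predict(clf_name, Xtr, ytr, Xte, seed, eta=1.0, tune_eta=False):
    if clf_name == "lrbsf":
        clf = LRBSFClassifier(eta=eta, tune_eta=tune_eta)
    elif clf_name == "svm":
        from sklearn.svm import SVC

        clf = SVC(random_state=seed)  # soft-margin RBF, one-vs-one multiclass
    else:
        raise ValidationError(f"unknown classifier {clf_name!r}")
    clf.fit(Xtr, ytr)
    return clf.predict(Xte)


def monte_carlo_cv(
    features,
    labels,
    classifier: str = "lrbsf",
    subset_sizes=(50,),
    n_reps: int = 100,
    test_fraction: float = 0.10,
    seed: int = 0,
    alpha: float = 0.05,
    eta: float = 1.0,
    tune_eta: bool = False,
) -> CVReport:
    """Repeated stratified 90/10 evaluation with in-fold feature selection.

    For two classes the Welch ranking of the pair is used directly; for
    K > 2 classes, per-pair rankings are computed on the training fold and
    the union of each pair's top-n forms the selected set for size n.
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    k = len(classes)
    if k < 2:
        raise ValidationError("need at least 2 classes")
    sizes = np.asarray(list(subset_sizes), dtype=int)
    splits = mc_splits(labels, test_fraction, n_reps, seed)
    pos = {c: i for i, c in enumerate(classes)}

    confusions = np.zeros((n_reps, len(sizes), k, k), dtype=int)
    test_sets = []
    for r, (train, test) in enumerate(splits):
        Xtr, ytr = values[train], labels[train]
        Xte, yte = values[test], labels[test]
        if k == 2:
            rankings = {tuple(classes): rank_features(Xtr, ytr, tuple(classes), alpha=alpha)}
        else:
            rankings = {
                pair: rank_features(Xtr, ytr, pair, alpha=alpha)
                for pair in combinations(classes.tolist(), 2)
            }
        for s, n_feat in enumerate(sizes):
            if k == 2:
                idx = next(iter(rankings.values())).top(n_feat)
            else:
                idx = union_top_n(rankings, n_feat)
            if len(idx) == 0:
                # nothing significant: fall back to the single best-p feature
                best = min(
                    rankings.values(), key=lambda res: res.p_values.min()
                )
                idx = np.array([int(np.argmin(best.p_values))])
            pred = _fit_predict(
                classifier, Xtr[:, idx], ytr, Xte[:, idx],
                seed=seed + r, eta=eta, tune_eta=tune_eta,
            )
            for yt, yp in zip(yte, pred):
                confusions[r, s, pos[yt], pos[yp]] += 1
        test_sets.append(test)
    return CVReport(
        confusions=confusions,
        subset_sizes=sizes,
        class_ids=classes,
        n_repetitions=n_reps,
        test_fraction=test_fraction,
        seed=seed,
        method=classifier,
        test_indices=test_sets,
    )


def pairwise_sweep(
    features, labels, subset_sizes=(50,), seed: int = 0, **cv_kwargs
) -> dict:
    """One CVReport per unordered class pair (K classes -> K(K-1)/2 runs).

    Each pair's run restricts the trials to the two classes; the split
    stream is derived deterministically from (seed, pair index).
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    out = {}
    for i, pair in enumerate(combinations(classes.tolist(), 2)):
        mask = np.isin(labels, pair)
        pair_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        out[pair] = monte_carlo_cv(
            values[mask], labels[mask], subset_sizes=subset_sizes,
            seed=pair_seed, **cv_kwargs,
        )
    return out


def confusion_stats(confusion) -> tuple:
    """(accuracy %, sensitivity %, specificity %) from a confusion matrix.

    For 2x2 (rows true, cols predicted, first class positive):
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).  For K > 2 only
    accuracy is defined; the other two are returned as None.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.size == 0:
        raise ValidationError("confusion matrix must be square and non-empty")
    if (c < 0).any():
        raise ValidationError("confusion counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValidationError("confusion matrix is empty (no counts)")
    acc = 100.0 * np.trace(c) / total
    if c.shape == (2, 2):
        tp, fn, fp, tn = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
        sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else np.nan
        spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan
        return float(acc), float(sens), float(spec)
    return float(acc), None, None


def permutation_chance(
    n_samples: int,
    n_classes: int = 2,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ChanceLevel:
    """Chance-level accuracy threshold at the (1 - alpha) quantile.

    Empirical: accuracy of uniform random guesses against balanced true
    labels, repeated ``n_permutations`` times; threshold is the empirical
    (1 - alpha) quantile (upper boundary, so the 'higher' quantile rule).
    Analytic: the binomial (1 - alpha) quantile, m/n with
    m = BinomPPF(1 - alpha; n, 1/K).  At n = 100, K = 2, alpha = 0.05 the
    analytic threshold is 58%.
    """
    if n_samples < 1 or n_classes < 2:
        raise ValidationError("need n_samples >= 1 and K >= 2")
    rng = np.random.default_rng(seed)
    true = np.arange(n_samples) % n_classes
    guesses = rng.integers(0, n_classes, size=(n_permutations, n_samples))
    accs = (guesses == true).mean(axis=1)
    empirical = 100.0 * float(np.quantile(accs, 1.0 - alpha, method="higher"))
    m = stats.binom.ppf(1.0 - alpha, n_samples, 1.0 / n_classes)
    analytic = 100.0 * float(m) / n_samples
    return ChanceLevel(
        n_samples=n_samples,
        n_classes=n_classes,
        alpha=alpha,
        n_permutations=n_permutations,
        empirical_pct=empirical,
        analytic_pct=analytic,
        null_accuracies=accs,
    )


def compare_methods(accuracy_tables: dict, reference: str) -> dict:
    """Paired t-tests (reference vs each method) and a one-way ANOVA.

    ``accuracy_tables`` maps method name -> per-condition accuracy array;
    all tables must be aligned (same conditions, same order).
    """
    if reference not in accuracy_tables:
        raise ValidationError(f"reference method {reference!r} not in tables")
    lengths = {k: len(np.asarray(v)) for k, v in accuracy_tables.items()}
    if len(set(lengths.values())) != 1:
        raise ValidationError(f"misaligned condition lists: {lengths}")
    ref = np.asarray(accuracy_tables[reference], dtype=float)
    paired = {}
    for name, vals in accuracy_tables.items():
        if name == reference:
            continue
        vals = np.asarray(vals, dtype=float)
        if np.allclose(vals, ref):
            paired[name] = {"t": 0.0, "p": 1.0}
        else:
            t, p = stats.ttest_rel(ref, vals)
            paired[name] = {"t": float(t), "p": float(p)}
    groups = [np.asarray(v, dtype=float) for v in accuracy_tables.values()]
    if len(groups) > 1:
        f, p_anova = stats.f_oneway(*groups)
        anova = {"F": float(f), "p": float(p_anova)}
    else:
        anova = {"F": np.nan, "p": np.nan}
    return {"paired_t": paired, "anova": anova}


def svm_baseline(features, labels, **cv_kwargs) -> CVReport:
    """The identical MC-CV protocol with an SVM replacing the LRBSF.

    Splits are shared with the LRBSF run at the same seed (the split
    stream depends only on seed, labels and test_fraction).
    """
    return monte_carlo_cv(features, labels, classifier="svm", **cv_kwargs)
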