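"""LRBSF classifier: KDE accuracy, log-LR oracles, decision rules."""

import numpy as np
import pytest

from eegfuse import (
    ClassDensityModel,
    DecisionRule,
    LRBSFClassifier,
    ValidationError,
    class_scores,
    decide_multiclass,
    decide_pairwise,
    fit_kde,
    loglr,
    select_eta,
    silverman_bandwidth,
)


def kde_logpdf_oracle(x, train, h):
    """Double-loop Gaussian kernel sum, independent of the implementation."""
    total = 0.0
    for t in train:
        total += np.exp(-0.5 * ((x - t) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    return np.log(max(total / len(train), 1e-300))


class TestFitKDE:
    def test_degenerate_sample_density_peaks_at_value(self):
        d = fit_kde([0.0, 0.0, 0.0, 0.0], fallback_scale=2.0)
        assert d.bandwidth == pytest.approx(2e-6)
        grid = np.linspace(-1, 1, 11)
        assert np.argmax(d.pdf(grid)) == 5  # maximal at 0

    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(0)
        d = fit_kde(rng.standard_normal(2000))
        assert d.pdf(0.0)[0] == pytest.approx(0.3989, abs=0.05)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        d = fit_kde(rng.normal(2.0, 3.0, size=200))
        grid = np.linspace(2 - 30, 2 + 30, 20001)
        integral = np.trapezoid(d.pdf(grid), grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_kde([1.0])

    def test_silverman_formula(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(100)
        sd = v.std(ddof=1)
        iqr_scale = (np.percentile(v, 75) - np.percentile(v, 25)) / 1.34
        expected = 0.9 * min(sd, iqr_scale) * 100 ** (-0.2)
        assert silverman_bandwidth(v) == pytest.approx(expected)


class TestLogLR:
    def _models(self, x1, x0, h1=None, h0=None):
        m1 = ClassDensityModel.fit(np.asarray(x1, float), class_id=1)
        m0 = ClassDensityModel.fit(np.asarray(x0, float), class_id=0)
        if h1 is not None:
            m1.bandwidths = np.asarray(h1, float)
        if h0 is not None:
            m0.bandwidths = np.asarray(h0, float)
        return m1, m0

    def test_identical_models_give_zero(self):
        x = np.random.default_rng(3).normal(size=(5, 2))
        m1, m0 = self._models(x, x)
        assert loglr(np.array([0.3, -0.7]), m1, m0) == pytest.approx(0.0, abs=1e-12)

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(4)
        m1, m0 = self._models(rng.normal(size=(4, 3)), rng.normal(1, 1, size=(6, 3)))
        x = rng.normal(size=3)
        assert loglr(x, m0, m1) == pytest.approx(-loglr(x, m1, m0), abs=1e-12)

    def test_matches_hand_kernel_sum(self):
        """2 features, 3 training points per class, hand-set bandwidths."""
        x1 = np.array([[0.0, 1.0], [0.5, 1.5], [1.0, 2.0]])
        x0 = np.array([[5.0, -1.0], [5.5, -1.5], [6.0, -2.0]])
        m1, m0 = self._models(x1, x0, h1=[0.7, 1.1], h0=[0.9, 0.6])
        x = np.array([0.4, 0.9])
        expected = sum(
            kde_logpdf_oracle(x[j], x1[:, j], [0.7, 1.1][j]) for j in range(2)
        ) - sum(kde_logpdf_oracle(x[j], x0[:, j], [0.9, 0.6][j]) for j in range(2))
        assert loglr(x, m1, m0) == pytest.approx(expected, abs=1e-10)

    def test_feature_set_mismatch_rejected(self):
        m1 = ClassDensityModel.fit(np.zeros((3, 2)) + [[0, 1], [1, 2], [2, 3]],
                                   class_id=1, feature_ids=[0, 1])
        m0 = ClassDensityModel.fit(np.zeros((3, 2)) + [[0, 1], [1, 2], [2, 3]],
                                   class_id=0, feature_ids=[4, 5])
        with pytest.raises(ValidationError):
            loglr(np.zeros(2), m1, m0)

    def test_far_out_point_stays_finite(self):
        rng = np.random.default_rng(5)
        m1, m0 = self._models(rng.normal(size=(5, 1)), rng.normal(size=(5, 1)))
        val = loglr(np.array([1e9]), m1, m0)
        assert np.isfinite(val)

    def test_monotone_toward_class1_mean_when_class0_flat(self):
        """Moving x toward class-1's mass raises the log-LR while class-0's
        density is floored (flat) in that region."""
        m1 = ClassDensityModel.fit(np.array([[-0.1], [0.0], [0.1]]), class_id=1)
        m0 = ClassDensityModel.fit(np.array([[99.9], [100.0], [100.1]]), class_id=0)
        xs = np.linspace(-5.0, 0.0, 21)
        vals = [loglr(np.array([x]), m1, m0) for x in xs]
        assert (np.diff(vals) >= -1e-12).all()


class TestDecidePairwise:
    def test_boundary_assigned_to_m1(self):
        rule = DecisionRule(eta=1.0, class_map=(0, 1))
        assert decide_pairwise(0.0, rule) == 1

    def test_below_threshold_is_m0(self):
        rule = DecisionRule(eta=1.0, class_map=(0, 1))
        assert decide_pairwise(-0.1, rule) == 0

    def test_eta_e_moves_threshold(self):
        rule = DecisionRule(eta=np.e, class_map=(0, 1))
        assert decide_pairwise(0.5, rule) == 0
        assert decide_pairwise(1.5, rule) == 1

    def test_nonpositive_eta_rejected(self):
        with pytest.raises(ValidationError):
            DecisionRule(eta=0.0)


class TestSelectEta:
    def test_separable_scores_reach_full_training_accuracy(self):
        scores = np.array([-3.0, -2.0, -1.5, 1.2, 2.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        eta = select_eta(scores, labels, m1_class=1)
        pred = (scores >= np.log(eta)).astype(int)
        assert (pred == labels).all()

    def test_all_equal_scores_give_eta_one(self):
        eta = select_eta(np.zeros(6), np.array([0, 0, 0, 1, 1, 1]), m1_class=1)
        assert eta == 1.0

    def test_random_labels_heldout_near_chance(self):
        """Threshold tuning on noise: training accuracy exceeds 1/2 only
        by optimization bias; accuracy on fresh held-out data stays ~1/2."""
        rng = np.random.default_rng(6)
        held, train = [], []
        for _ in range(100):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)  # independent of scores
            eta = select_eta(scores[:30], labels[:30], m1_class=1)
            tr_pred = (scores[:30] >= np.log(eta)).astype(int)
            train.append((tr_pred == labels[:30]).mean())
            pred = (scores[30:] >= np.log(eta)).astype(int)
            held.append((pred == labels[30:]).mean())
        assert np.mean(train) > 0.5  # optimization bias on the training fold
        se = np.std(held, ddof=1) / np.sqrt(len(held))
        assert abs(np.mean(held) - 0.5) < 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            select_eta(np.arange(4.0), np.ones(4), m1_class=1)


class TestClassScores:
    def test_two_class_scores_reduce_to_loglr(self):
        rng = np.random.default_rng(7)
        m1 = ClassDensityModel.fit(rng.normal(size=(5, 3)), class_id=1)
        m2 = ClassDensityModel.fit(rng.normal(2, 1, size=(5, 3)), class_id=2)
        x = rng.normal(size=3)
        s = class_scores(x, [m1, m2])
        assert s[0] - s[1] == pytest.approx(loglr(x, m1, m2), abs=1e-12)

    def test_identical_training_gives_equal_scores(self):
        data = np.random.default_rng(8).normal(size=(4, 2))
        models = [ClassDensityModel.fit(data, class_id=c) for c in (1, 2, 3)]
        s = class_scores(np.array([0.1, 0.2]), models)
        assert np.ptp(s) < 1e-12

    def test_three_class_hand_oracle(self):
        trains = [np.array([[0.0], [1.0]]), np.array([[5.0], [6.0]]),
                  np.array([[-4.0], [-5.0]])]
        models = [ClassDensityModel.fit(t, class_id=c + 1) for c, t in enumerate(trains)]
        x = np.array([0.5])
        s = class_scores(x, models)
        for c in range(3):
            exp = kde_logpdf_oracle(0.5, trains[c][:, 0], models[c].bandwidths[0])
            assert s[c] == pytest.approx(exp, abs=1e-10)


class TestDecideMulticlass:
    def test_argmax(self):
        assert decide_multiclass(np.array([-3.0, -1.0, -2.0])) == 2

    def test_tie_goes_to_smallest_class(self):
        assert decide_multiclass(np.zeros(4)) == 1

    def test_consistent_with_pairwise_at_eta_one(self):
        rng = np.random.default_rng(9)
        m1 = ClassDensityModel.fit(rng.normal(size=(5, 2)), class_id=1)
        m2 = ClassDensityModel.fit(rng.normal(3, 1, size=(5, 2)), class_id=2)
        rule = DecisionRule(eta=1.0, class_map=(2, 1))
        for _ in range(20):
            x = rng.normal(1.5, 2.0, size=2)
            s = class_scores(x, [m1, m2])
            assert decide_multiclass(s, class_ids=[1, 2]) == decide_pairwise(
                loglr(x, m1, m2), rule
            )


class TestClassifierBehavior:
    def test_null_calibration(self):
        """Two classes from one distribution: held-out accuracy within
        3 SE of 1/2 over 100 seeded repetitions."""
        accs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(50, 3))
            y = np.repeat([1, 2], 25)
            clf = LRBSFClassifier().fit(X[:40], y[:40])
            accs.append((clf.predict(X[40:]) == y[40:]).mean())
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * se

    def test_strong_feature_high_accuracy(self):
        """Effect of 5 sd on one feature: held-out pairwise accuracy >= 95%
        at 50 trials per class."""
        rng = np.random.default_rng(10)
        accs = []
        for _ in range(20):
            X = rng.normal(size=(100, 5))
            y = np.repeat([1, 2], 50)
            X[y == 2, 0] += 5.0
            idx = rng.permutation(100)
            X, y = X[idx], y[idx]
            clf = LRBSFClassifier().fit(X[:80], y[:80])
            accs.append((clf.predict(X[80:]) == y[80:]).mean())
        assert np.mean(accs) >= 0.95

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 4))
        y = np.repeat([1, 2], 10)
        clf = LRBSFClassifier().fit(X, y)
        p = tmp_path / "model.json"
        clf.save(p)
        back = LRBSFClassifier.load(p)
        Xt = rng.normal(size=(15, 4))
        np.testing.assert_array_equal(back.predict(Xt), clf.predict(Xt))
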