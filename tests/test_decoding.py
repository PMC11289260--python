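import numpy as np
import pytest

import popdyn as P
from popdyn.binning import TrialGrid
from popdyn.decoding import CHANCE, delta_decoding, relative_performance


class DiagonalGaussianOracle:
    """Independent hand-rolled pooled-variance diagonal classifier."""

    def fit(self, X, y):
        self.classes = np.unique(y)
        self.means = np.stack([X[y == c].mean(axis=0) for c in self.classes])
        resid = X - self.means[np.searchsorted(self.classes, y)]
        self.var = (resid**2).sum(axis=0) / (len(y) - len(self.classes))
        return self

    def predict(self, X):
        # pooled-variance Gaussian log-likelihood per class
        ll = np.stack(
            [-0.5 * (((X - m) ** 2) / self.var).sum(axis=1) for m in self.means]
        )
        return self.classes[np.argmax(ll, axis=0)]


def _gaussian_classes(rng, n_per=20, p=8, sep=3.0, K=6):
    means = rng.normal(0, sep, (K, p))
    X = np.concatenate([rng.normal(m, 1.0, (n_per, p)) for m in means])
    y = np.repeat(np.arange(K), n_per)
    return X, y


class TestLdaCore:
    def test_separated_classes_perfectly_decoded(self, rng):
        X, y = _gaussian_classes(rng, sep=8.0)
        clf = P.RegularisedLDA(gamma=1.0).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.99

    def test_gamma_one_matches_diagonal_oracle_prediction_for_prediction(
        self, rng
    ):
        # ridge jitter off so the covariances agree exactly
        for _ in range(5):
            X, y = _gaussian_classes(rng, n_per=20, sep=1.0)
            ours = P.RegularisedLDA(gamma=1.0, ridge=0.0).fit(X, y)
            oracle = DiagonalGaussianOracle().fit(X, y)
            Xt = rng.normal(0, 2.0, (30, X.shape[1]))
            np.testing.assert_array_equal(ours.predict(Xt), oracle.predict(Xt))

    def test_delta_threshold_drops_uninformative_features(self, rng):
        X, y = _gaussian_classes(rng, p=4, sep=4.0)
        noise = rng.normal(0, 1.0, (len(y), 6))  # pure-noise predictors
        Xa = np.concatenate([X, noise], axis=1)
        clf = P.RegularisedLDA(gamma=1.0, delta=1.0).fit(Xa, y)
        assert set(clf.keep_) <= set(range(4))
        assert (clf.predict(Xa) == y).mean() > 0.95

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            P.DecoderSpec(gamma=1.5)
        with pytest.raises(ValueError):
            P.DecoderSpec(n_folds=1)


class TestFormulaIdentities:
    def test_delta_is_one_when_shuffled_equals_intact(self):
        acc = np.array([0.4, 0.8, 0.25])
        np.testing.assert_allclose(delta_decoding(acc, acc), 1.0)

    def test_delta_missing_at_chance(self):
        assert np.isnan(delta_decoding(CHANCE, 0.5))

    def test_delta_hand_table(self):
        # (shuffled - chance) / (intact - chance) on hand numbers
        got = delta_decoding(np.array([0.5]), np.array([1 / 3]))
        np.testing.assert_allclose(got, (1 / 3 - 1 / 6) / (0.5 - 1 / 6))

    def test_relative_performance_one_under_perfect_generalisation(self):
        A = np.full((5, 5), 0.7)
        np.testing.assert_allclose(relative_performance(A), 1.0)

    def test_relative_performance_hand_table(self):
        A = np.array([[0.9, 1 / 6], [1 / 6, 0.9]])
        rel = relative_performance(A)
        expect = ((0.9 + 1 / 6) / 2 - 1 / 6) / (0.9 - 1 / 6)
        np.testing.assert_allclose(rel, expect)

    def test_relative_performance_missing_below_chance(self):
        A = np.full((3, 3), 0.1)
        assert np.all(np.isnan(relative_performance(A)))


def _windowed(X, n_bins=40):
    """Tile a (trials, units) feature matrix into constant bins."""
    return np.repeat(X[:, :, None] / n_bins, n_bins, axis=2)


class TestSlidingDecoding:
    GRID = TrialGrid(0.0, 400.0, 0.0)  # 40 bins

    def test_shuffled_labels_are_at_chance(self, rng):
        X, y = _gaussian_classes(rng, n_per=15, sep=5.0)
        y = rng.permutation(y)
        counts = _windowed(X + 10)
        spec = P.DecoderSpec(gamma=1.0, n_repeats=3, step_bins=10)
        res = P.decode_sliding(counts, y, spec, grid=self.GRID)
        n_eff = len(y)
        sd = np.sqrt(CHANCE * (1 - CHANCE) / n_eff)
        assert np.all(np.abs(res.accuracy - CHANCE) < 3.5 * sd)

    def test_strong_tuning_decoded_above_ninety_percent(self, rng):
        X, y = _gaussian_classes(rng, n_per=15, sep=8.0)
        counts = _windowed(X + 20)
        spec = P.DecoderSpec(gamma=1.0, n_repeats=2, step_bins=10)
        res = P.decode_sliding(counts, y, spec, grid=self.GRID)
        assert res.accuracy.mean() > 0.9

    def test_prestimulus_windows_at_chance_on_stimulus_locked_data(self, rng):
        # information appears only after onset
        n_per, p = 15, 6
        y = np.repeat(np.arange(6), n_per)
        grid = TrialGrid(200.0, 400.0, 0.0)  # 20 pre bins + 40 stim bins
        counts = rng.poisson(1.0, (len(y), p, 60)).astype(float)
        means = rng.normal(0, 4.0, (6, p))
        counts[:, :, 20:] += np.repeat(means[y][:, :, None], 40, axis=2)
        spec = P.DecoderSpec(gamma=1.0, n_repeats=2, step_bins=10)
        res = P.decode_sliding(counts, y, spec, grid=grid)
        pre = res.window_mid_ms < -40
        stim = res.window_mid_ms > 40
        sd = np.sqrt(CHANCE * (1 - CHANCE) / len(y))
        assert np.all(np.abs(res.accuracy[pre] - CHANCE) < 3.5 * sd)
        assert res.accuracy[stim].mean() > 0.9

    def test_fixed_seed_reproduces_accuracies_exactly(self, rng):
        X, y = _gaussian_classes(rng, n_per=10, sep=2.0)
        counts = _windowed(X + 10)
        spec = P.DecoderSpec(gamma=0.5, n_repeats=2, step_bins=20, seed=9)
        a = P.decode_sliding(counts, y, spec, grid=self.GRID)
        b = P.decode_sliding(counts, y, spec, grid=self.GRID)
        np.testing.assert_array_equal(a.per_repeat, b.per_repeat)

    def test_class_below_fold_count_rejected(self, rng):
        counts = rng.poisson(1.0, (4, 3, 40)).astype(float)
        with pytest.raises(ValueError):
            P.decode_sliding(counts, np.array([0, 0, 1, 1]),
                             P.DecoderSpec(n_folds=3), grid=self.GRID)


class TestShuffleComparison:
    def test_independent_noise_leaves_delta_near_one(self, rng):
        # without noise correlations, trial shuffling changes nothing
        # systematically, so Delta ~ 1 in well-decoded windows
        X, y = _gaussian_classes(rng, n_per=18, sep=6.0)
        counts = _windowed(X + 20, n_bins=100)
        grid = TrialGrid(0.0, 1000.0, 0.0)
        spec = P.DecoderSpec(gamma=0.5, n_repeats=2, step_bins=20, seed=3)
        sc = P.shuffle_comparison(counts, y, spec, grid=grid)
        assert np.nanmedian(sc.delta) == pytest.approx(1.0, abs=0.1)


class TestCrossTime:
    def test_stationary_code_generalises_fully(self, rng):
        X, y = _gaussian_classes(rng, n_per=16, sep=6.0)
        counts = _windowed(X + 20, n_bins=40)
        grid = TrialGrid(0.0, 400.0, 0.0)
        ctm = P.cross_time(counts, y, P.DecoderSpec(gamma=1.0, n_folds=2,
                                                    n_repeats=2), grid=grid)
        assert np.all(ctm.relative_performance > 0.9)

    def test_orthogonal_rotation_kills_generalisation(self, rng):
        # class means rotate to an orthogonal subspace mid-stimulus
        n_per, p = 16, 12
        y = np.repeat(np.arange(6), n_per)
        means_a = np.zeros((6, p))
        means_a[:, :6] = np.eye(6) * 8.0
        means_b = np.zeros((6, p))
        means_b[:, 6:] = np.eye(6) * 8.0
        counts = np.empty((len(y), p, 40))
        counts[:, :, :20] = _windowed(
            rng.normal(means_a[y] + 20, 1.0), n_bins=20)
        counts[:, :, 20:] = _windowed(
            rng.normal(means_b[y] + 20, 1.0), n_bins=20)
        grid = TrialGrid(0.0, 400.0, 0.0)
        ctm = P.cross_time(counts, y, P.DecoderSpec(gamma=1.0, n_folds=2,
                                                    n_repeats=2), grid=grid)
        # early-trained decoders fail on late windows and vice versa
        assert np.all(ctm.relative_performance < 0.75)
        assert np.all(np.diag(ctm.accuracy) > 0.9)


class TestTrajectoryDecodingAndPopulationCurves:
    def test_disjoint_latent_steady_states_decoded(self, rng):
        y = np.repeat(np.arange(6), 10)
        lat = rng.normal(0, 0.2, (60, 2, 200))
        # separate per-speed positions late in the stimulus
        offsets = np.linspace(-3, 3, 6)
        lat[:, 0, 80:120] += offsets[y][:, None]
        res = P.decode_trajectories(lat, y, n_repeats=2)
        late = (res.window_mid_ms > 650) & (res.window_mid_ms < 950)
        pre = res.window_mid_ms < -60
        assert res.accuracy[late].mean() > 0.9
        sd = np.sqrt(CHANCE * (1 - CHANCE) / 60)
        assert np.all(np.abs(res.accuracy[pre] - CHANCE) < 3.5 * sd)

    def test_accuracy_grows_with_population_size(self, rng):
        y = np.repeat(np.arange(6), 12)
        means = rng.normal(0, 0.8, (6, 30))
        X = rng.normal(means[y] + 5, 1.0)
        counts = _windowed(X, n_bins=120)
        grid = TrialGrid(0.0, 1200.0, 0.0)
        pc = P.population_curves(
            counts, y, [1, 8, 30], P.DecoderSpec(gamma=1.0, n_repeats=1),
            window_ms=(0.0, 1000.0), n_repetitions=8, grid=grid,
        )
        assert pc.mean_accuracy[2] > pc.mean_accuracy[0]
        assert pc.mean_accuracy[0] < 0.5  # single weak unit near chance

    def test_oversized_population_rejected(self, rng):
        counts = rng.poisson(1.0, (36, 5, 40)).astype(float)
        y = np.repeat(np.arange(6), 6)
        with pytest.raises(ValueError):
            P.population_curves(counts, y, [10], grid=TrialGrid(0, 400, 0))
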