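"""Regularised LDA decoding of stimulus speed.

The decoder is linear discriminant analysis with class means and a
pooled covariance that blends the full and diagonal estimates,

    Sigma_gamma = (1 - gamma) * Sigma + gamma * diag(Sigma),

so gamma = 1 forces the decoder to ignore correlations between units
(independent-neuron decoding) and gamma = 0 uses the full covariance.
A second hyperparameter delta thresholds standardised discriminant
coefficients: predictors whose coefficient magnitude falls below delta
are dropped and the model refit once.  Chance performance with six
stimulus speeds is 1/6.

Provided protocols: sliding-window decoding (100 ms window, 10 ms step,
stratified 3-fold CV x 5 repeats with optional inner 5-fold grid search
over delta/gamma), intact-vs-trial-shuffled comparison (Delta decoding),
cross-time generalisation on non-overlapping 100 ms windows (2-fold x 5
repeats), single-trial latent-trajectory decoding (50 ms windows) and
population-size curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .binning import (
    BIN_MS,
    DEFAULT_GRID,
    TrialGrid,
    sliding_window_sums,
    window_mid_ms,
    window_starts,
)

CHANCE = 1.0 / 6.0


@dataclass(frozen=True)
class DecoderSpec:
    """Decoding protocol configuration."""

    gamma: float = 1.0
    delta: float = 0.0
    gamma_grid: tuple = ()  # empty -> no gamma search
    delta_grid: tuple = ()  # empty -> no delta search
    n_folds: int = 3
    n_repeats: int = 5
    inner_folds: int = 5
    window_bins: int = 10  # 100 ms
    step_bins: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_folds < 2:
            raise ValueError("need >= 2 folds")


class RegularisedLDA:
    """LDA with blended pooled covariance and coefficient thresholding."""

    def __init__(self, gamma: float = 1.0, delta: float = 0.0,
                 ridge: float = 1e-8):
        self.gamma = gamma
        self.delta = delta
        self.ridge = ridge

    def _solve(self, X, y):
        classes = np.unique(y)
        K = len(classes)
        n, p = X.shape
        means = np.stack([X[y == c].mean(axis=0) for c in classes])
        resid = X - means[np.searchsorted(classes, y)]
        if n - K <= 0:
            raise ValueError("too few trials for pooled covariance")
        cov = (resid.T @ resid) / (n - K)
        cov = (1.0 - self.gamma) * cov + self.gamma * np.diag(np.diag(cov))
        jitter = self.ridge * max(np.trace(cov) / p, 1e-300)
        cov = cov + jitter * np.eye(p)
        W = np.linalg.solve(cov, means.T)  # (p, K)
        const = -0.5 * np.einsum("kp,pk->k", means, W)
        return classes, means, cov, W, const

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegularisedLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need >= 2 classes")
        classes, means, cov, W, const = self._solve(X, y)
        self.keep_ = np.arange(X.shape[1])
        if self.delta > 0:
            sd = np.sqrt(np.diag(cov))
            coef = np.abs(W - W.mean(axis=1, keepdims=True)) * sd[:, None]
            score = coef.max(axis=1)
            keep = np.flatnonzero(score >= self.delta)
            if keep.size == 0:
                keep = np.array([int(np.argmax(score))])
            if keep.size < X.shape[1]:
                classes, means, cov, W, const = self._solve(X[:, keep], y)
                self.keep_ = keep
        self.classes_, self.coef_, self.const_ = classes, W, const
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.keep_]
        return X @ self.coef_ + self.const_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def fit_predict_lda(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    spec: DecoderSpec = DecoderSpec(),
) -> np.ndarray:
    """Fit the regularised LDA on training data and predict test labels."""
    clf = RegularisedLDA(gamma=spec.gamma, delta=spec.delta)
    return clf.fit(train_X, train_y).predict(test_X)


def _stratified_folds(y, n_folds, rng):
    folds = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        for k in range(n_folds):
            folds[k].extend(idx[k::n_folds])
    return [np.array(sorted(f), dtype=int) for f in folds]


def _grid_candidates(spec: DecoderSpec):
    gammas = spec.gamma_grid or (spec.gamma,)
    deltas = spec.delta_grid or (spec.delta,)
    return [(g, d) for g in gammas for d in deltas]


def _inner_select(X, y, spec: DecoderSpec, rng) -> tuple[float, float]:
    """Inner-CV grid search over (gamma, delta); deterministic given rng."""
    cands = _grid_candidates(spec)
    if len(cands) == 1:
        return cands[0]
    folds = _stratified_folds(y, min(spec.inner_folds,
                                     np.bincount(np.unique(y, return_inverse=True)[1]).min()),
                              rng)
    best, best_acc = cands[0], -1.0
    for g, d in cands:
        acc = 0.0
        for k, test in enumerate(folds):
            mask = np.ones(len(y), dtype=bool)
            mask[test] = False
            pred = fit_predict_lda(X[mask], y[mask], X[test],
                                   replace(spec, gamma=g, delta=d))
            acc += float(np.mean(pred == y[test]))
        acc /= len(folds)
        if acc > best_acc + 1e-12:
            best, best_acc = (g, d), acc
    return best


def _cv_accuracy(X, y, spec: DecoderSpec, rng) -> np.ndarray:
    """Outer-CV accuracy per repeat for one feature matrix."""
    out = np.empty(spec.n_repeats)
    for r in range(spec.n_repeats):
        folds = _stratified_folds(y, spec.n_folds, rng)
        correct = 0
        for test in folds:
            mask = np.ones(len(y), dtype=bool)
            mask[test] = False
            g, d = _inner_select(X[mask], y[mask], spec, rng)
            pred = fit_predict_lda(X[mask], y[mask], X[test],
                                   replace(spec, gamma=g, delta=d))
            correct += int(np.sum(pred == y[test]))
        out[r] = correct / len(y)
    return out


@dataclass
class DecodingResult:
    window_mid_ms: np.ndarray
    accuracy: np.ndarray  # (W,)
    per_repeat: np.ndarray  # (W, n_repeats)
    chance: float = CHANCE


def decode_sliding(
    counts: np.ndarray,
    labels: np.ndarray,
    spec: DecoderSpec = DecoderSpec(),
    grid: TrialGrid = DEFAULT_GRID,
) -> DecodingResult:
    """Sliding-window cross-validated decoding accuracy.

    ``counts`` is (n_trials, n_units, n_bins); features per window are
    mean binned counts.  Accuracy per window is the mean over stratified
    folds and repeats of the fraction of held-out trials predicted
    correctly.
    """
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(labels)
    _check_counts_per_class(y, spec.n_folds)
    rng = np.random.default_rng(spec.seed)
    Wc = sliding_window_sums(counts, spec.window_bins, spec.step_bins, axis=-1) \
        / spec.window_bins
    starts = window_starts(counts.shape[2], spec.window_bins, spec.step_bins)
    mids = window_mid_ms(starts, spec.window_bins, grid)
    per_repeat = np.empty((len(starts), spec.n_repeats))
    for w in range(len(starts)):
        per_repeat[w] = _cv_accuracy(Wc[:, :, w], y, spec, rng)
    return DecodingResult(window_mid_ms=mids, accuracy=per_repeat.mean(axis=1),
                          per_repeat=per_repeat)


def _check_counts_per_class(y, n_folds):
    _, cnt = np.unique(y, return_counts=True)
    if cnt.min() < n_folds:
        raise ValueError("every class needs at least n_folds trials")


def _shuffle_within_conditions(counts, y, rng):
    """Permute trials within condition independently per unit."""
    out = counts.copy()
    n, P = counts.shape[:2]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        for p in range(P):
            out[idx, p] = counts[idx[rng.permutation(len(idx))], p]
    return out


def delta_decoding(intact, shuffled, chance: float = CHANCE):
    """Fractional performance change, (shuffled - chance)/(intact - chance).

    1 means disrupting noise correlations leaves performance unchanged;
    > 1 means shuffling *helps* (information-limiting correlations);
    NaN where intact performance equals chance.
    """
    intact = np.asarray(intact, dtype=float)
    shuffled = np.asarray(shuffled, dtype=float)
    den = intact - chance
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, (shuffled - chance) / den, np.nan)


def relative_performance(accuracy: np.ndarray, window_idx=None,
                         chance: float = CHANCE) -> np.ndarray:
    """Cross-time generalisation relative to matched train=test decoders.

    ``accuracy`` is a (train, test) window matrix; for each train window
    the mean accuracy over the selected test windows is compared with
    the mean train=test (diagonal) accuracy over the same windows, both
    chance-subtracted.  1 means a decoder generalises as well as
    decoders trained in place; NaN when the diagonal mean is at or below
    chance.
    """
    A = np.asarray(accuracy, dtype=float)
    idx = np.arange(A.shape[0]) if window_idx is None else np.asarray(window_idx)
    den = np.mean(A[idx, idx]) - chance
    if den <= 0:
        return np.full(len(idx), np.nan)
    return (A[np.ix_(idx, idx)].mean(axis=1) - chance) / den


@dataclass
class ShuffleComparison:
    window_mid_ms: np.ndarray
    intact: np.ndarray
    shuffled: np.ndarray
    delta: np.ndarray  # Delta decoding performance per window
    chance: float = CHANCE


def shuffle_comparison(
    counts: np.ndarray,
    labels: np.ndarray,
    spec: DecoderSpec | None = None,
    grid: TrialGrid = DEFAULT_GRID,
) -> ShuffleComparison:
    """Fractional performance change after disrupting noise correlations.

    Decoding runs on 100 ms windows with a 20 ms step, restricted to the
    stimulus period, with the blended-covariance decoder; trial-shuffled
    counts (within-condition, per unit) are decoded identically and

        Delta = (shuffled - chance) / (intact - chance)

    per window.  Windows where intact accuracy equals chance yield NaN.
    """
    if spec is None:
        spec = DecoderSpec(gamma=0.5, step_bins=2)
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    stim = grid.slice_ms(0.0, grid.stim_ms)
    sub = counts[:, :, stim]
    shuf = _shuffle_within_conditions(sub, y, rng)
    sub_grid = TrialGrid(pre_ms=0.0, stim_ms=grid.stim_ms, post_ms=0.0)
    intact = decode_sliding(sub, y, spec, grid=sub_grid)
    shuffled = decode_sliding(shuf, y, replace(spec, seed=spec.seed + 1),
                              grid=sub_grid)
    delta = delta_decoding(intact.accuracy, shuffled.accuracy)
    return ShuffleComparison(
        window_mid_ms=intact.window_mid_ms, intact=intact.accuracy,
        shuffled=shuffled.accuracy, delta=delta,
    )


@dataclass
class CrossTimeMatrix:
    window_mid_ms: np.ndarray
    accuracy: np.ndarray  # (W_train, W_test)
    relative_performance: np.ndarray  # per stimulus-period train window
    stimulus_windows: np.ndarray  # indices of stimulus-period windows
    chance: float = CHANCE


def cross_time(
    counts: np.ndarray,
    labels: np.ndarray,
    spec: DecoderSpec | None = None,
    grid: TrialGrid = DEFAULT_GRID,
) -> CrossTimeMatrix:
    """Train x test accuracy on non-overlapping 100 ms windows.

    Decoders are trained on half the trials (stratified 2-fold) in each
    window and tested on the held-out half in every window; 5 repeats.
    Relative performance of a train window t compares its
    mean accuracy across stimulus-period test windows with the mean
    train=test accuracy over the stimulus period.
    """
    if spec is None:
        spec = DecoderSpec(gamma=0.5, n_folds=2, n_repeats=5)
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(labels)
    _check_counts_per_class(y, 2)
    rng = np.random.default_rng(spec.seed)
    wb = spec.window_bins
    starts = np.arange(0, counts.shape[2] - wb + 1, wb)
    mids = window_mid_ms(starts, wb, grid)
    Wc = np.stack(
        [counts[:, :, s : s + wb].mean(axis=2) for s in starts], axis=2
    )  # (trials, units, W)
    nW = len(starts)
    acc = np.zeros((nW, nW))
    for _ in range(spec.n_repeats):
        folds = _stratified_folds(y, 2, rng)
        for half in range(2):
            train = folds[half]
            test = folds[1 - half]
            for wt in range(nW):
                g, d = _inner_select(Wc[train, :, wt], y[train], spec, rng)
                clf = RegularisedLDA(gamma=g, delta=d).fit(
                    Wc[train, :, wt], y[train]
                )
                for wx in range(nW):
                    pred = clf.predict(Wc[test, :, wx])
                    acc[wt, wx] += np.mean(pred == y[test])
    acc /= spec.n_repeats * 2
    half_ms = wb * BIN_MS / 2.0
    stim_idx = np.flatnonzero(
        (mids - half_ms >= -1e-9) & (mids + half_ms <= grid.stim_ms + 1e-9)
    )
    rel = relative_performance(acc, stim_idx)
    return CrossTimeMatrix(
        window_mid_ms=mids, accuracy=acc, relative_performance=rel,
        stimulus_windows=stim_idx,
    )


def decode_trajectories(
    latents: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    window_bins: int = 5,
    step_bins: int = 1,
    n_folds: int = 3,
    n_repeats: int = 10,
    grid: TrialGrid = DEFAULT_GRID,
) -> DecodingResult:
    """Decode stimulus speed from single-trial latent trajectories.

    ``latents`` is (n_trials, m, n_bins); features per 50 ms window are
    mean m-dimensional positions.  Full-covariance LDA without
    hyperparameter search, stratified 3-fold CV x 10 repeats.
    """
    spec = DecoderSpec(gamma=0.0, n_folds=n_folds, n_repeats=n_repeats,
                       window_bins=window_bins, step_bins=step_bins, seed=seed)
    return decode_sliding(latents, labels, spec, grid=grid)


@dataclass
class PopulationCurve:
    sizes: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    n_repetitions: int


def population_curves(
    counts: np.ndarray,
    labels: np.ndarray,
    sizes,
    spec: DecoderSpec = DecoderSpec(n_repeats=1),
    window_ms: tuple = (0.0, 1000.0),
    n_repetitions: int | None = None,
    max_repetitions: int = 20,
    grid: TrialGrid = DEFAULT_GRID,
) -> PopulationCurve:
    """Decoding accuracy as a function of population size.

    For each requested size, random unit subsets are drawn independently
    per repetition and decoded from their stimulus-period mean counts
    (single window by default).  Repetition count defaults to half the
    available units, capped.
    """
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(labels)
    P = counts.shape[1]
    sizes = np.asarray(list(sizes), dtype=int)
    if np.any(sizes > P):
        raise ValueError("population size exceeds available units")
    if n_repetitions is None:
        n_repetitions = min(int(np.ceil(P / 2)), max_repetitions)
    rng = np.random.default_rng(spec.seed)
    sel = grid.slice_ms(*window_ms)
    X = counts[:, :, sel].mean(axis=2)
    mean_acc = np.empty(len(sizes))
    sd_acc = np.empty(len(sizes))
    for i, size in enumerate(sizes):
        accs = []
        for _ in range(n_repetitions):
            units = rng.choice(P, size=size, replace=False)
            accs.append(_cv_accuracy(X[:, units], y, spec, rng).mean())
        mean_acc[i] = np.mean(accs)
        sd_acc[i] = np.std(accs)
    return PopulationCurve(sizes=sizes, mean_accuracy=mean_acc,
                           sd_accuracy=sd_acc, n_repetitions=n_repetitions)
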