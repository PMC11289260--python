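"""Sliding-window cross-validated tuning strength and tuning bouts.

Tuning strength of a unit in a 200 ms window is a cross-validated
coefficient of determination: per fold, a *trained* tuning-curve model
(per-speed mean count on the training trials) and a *null* model (grand
training mean) each predict the *test* tuning curve, and

    R^2 = 1 - SS_model / SS_null       if SS_model <= SS_null
    R^2 = -1 + SS_null / SS_model      otherwise

so R^2 is bounded in [-1, 1] and both branches meet at 0 when the
trained model is no better than the null.  The statistic is averaged
over 3 stratified folds x 10 re-randomised repeats, and compared per
window against the 95th percentile of a label-shuffle null.  A unit is
*tuned* where R^2 >= 0.1 and R^2 >= the null 95th percentile for at
least 5 consecutive windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import (
    BIN_MS,
    DEFAULT_GRID,
    TrialGrid,
    sliding_window_sums,
    window_mid_ms,
    window_starts,
)

WINDOW_BINS = 20  # 200 ms
BOUT_R2_THRESHOLD = 0.1
BOUT_MIN_RUN = 5


@dataclass
class TuningProfile:
    window_mid_ms: np.ndarray
    r2: np.ndarray
    null95: np.ndarray
    bouts: list  # [(start_mid_ms, finish_mid_ms)]
    tuned: bool
    start_ms: float
    finish_ms: float
    duration_ms: float


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Random fold assignment with balanced speed labels per fold."""
    folds: list[list] = [[] for _ in range(n_folds)]
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        for k in range(n_folds):
            folds[k].extend(idx[k::n_folds])
    return [np.array(sorted(f), dtype=int) for f in folds]


def _r2_folds(
    counts: np.ndarray,
    labels: np.ndarray,
    folds: list[np.ndarray],
) -> np.ndarray:
    """Mean branched cross-validated R^2 over folds.

    ``counts`` is (n_trials,) or (n_trials, n_windows); the return value
    is scalar or (n_windows,).  Missing SS_null (zero) yields NaN.
    """
    counts = np.asarray(counts, dtype=float)
    squeeze = counts.ndim == 1
    C = counts[:, None] if squeeze else counts
    ulabs = np.unique(labels)
    out = np.zeros(C.shape[1])
    for test_idx in folds:
        mask = np.zeros(len(labels), dtype=bool)
        mask[test_idx] = True
        train_idx = np.flatnonzero(~mask)
        trained = np.stack(
            [C[train_idx][labels[train_idx] == s].mean(axis=0) for s in ulabs]
        )
        test = np.stack([C[test_idx][labels[test_idx] == s].mean(axis=0)
                         for s in ulabs])
        null = C[train_idx].mean(axis=0)
        ss_model = ((trained - test) ** 2).sum(axis=0)
        ss_null = ((null[None, :] - test) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(
                ss_model <= ss_null,
                1.0 - ss_model / ss_null,
                -1.0 + ss_null / ss_model,
            )
        r2 = np.where(ss_null == 0, np.nan, r2)
        out = out + r2
    out = out / len(folds)
    return float(out[0]) if squeeze else out


def tuning_strength(
    counts: np.ndarray,
    speed_labels: np.ndarray,
    rng: np.random.Generator | int = 0,
    n_folds: int = 3,
    n_repeats: int = 10,
) -> float | np.ndarray:
    """Cross-validated tuning R^2 (mean of folds x repeats).

    ``counts`` may be per-trial scalars (one window) or a
    (n_trials, n_windows) array evaluated per window.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    labels = np.asarray(speed_labels)
    for lab in np.unique(labels):
        if (labels == lab).sum() < n_folds:
            raise ValueError(f"need >= {n_folds} trials per speed ({lab!r})")
    acc = None
    for _ in range(n_repeats):
        folds = _stratified_folds(labels, n_folds, rng)
        r = _r2_folds(counts, labels, folds)
        acc = r if acc is None else acc + r
    return acc / n_repeats


def tuning_profile(
    trial_counts: np.ndarray,
    speed_labels: np.ndarray,
    rng: np.random.Generator | int = 0,
    n_folds: int = 3,
    n_repeats: int = 10,
    n_shuffles: int = 100,
    window_bins: int = WINDOW_BINS,
    step_bins: int = 1,
    grid: TrialGrid = DEFAULT_GRID,
) -> TuningProfile:
    """Sliding-window tuning R^2 with a shuffle null and bout detection.

    ``trial_counts`` is (n_trials, n_bins) on the 10 ms grid.  The null
    permutes speed labels across trials (one CV evaluation per shuffle)
    and takes the per-window 95th percentile.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    labels = np.asarray(speed_labels)
    W = sliding_window_sums(np.asarray(trial_counts, dtype=float),
                            window_bins, step_bins, axis=-1)
    starts = window_starts(trial_counts.shape[1], window_bins, step_bins)
    mids = window_mid_ms(starts, window_bins, grid)

    r2 = tuning_strength(W, labels, rng=rng, n_folds=n_folds, n_repeats=n_repeats)
    null = np.empty((n_shuffles, W.shape[1]))
    for s in range(n_shuffles):
        perm_labels = labels[rng.permutation(len(labels))]
        folds = _stratified_folds(perm_labels, n_folds, rng)
        null[s] = _r2_folds(W, perm_labels, folds)
    null95 = np.nanpercentile(null, 95.0, axis=0)
    return detect_bouts(r2, null95, mids)


def detect_bouts(
    r2: np.ndarray,
    null95: np.ndarray,
    window_mid_ms: np.ndarray,
    r2_threshold: float = BOUT_R2_THRESHOLD,
    min_run: int = BOUT_MIN_RUN,
) -> TuningProfile:
    """Run-length detection of tuning bouts on a complete profile.

    A bout is >= ``min_run`` consecutive windows with R^2 above both the
    fixed threshold and the shuffle-null 95th percentile.  The start time
    is the midpoint of the first window of the first bout, the finish
    the midpoint of the last window of the last bout, and the duration
    counts 10 ms steps over all bouts.
    """
    r2 = np.asarray(r2, dtype=float)
    valid = (r2 >= r2_threshold) & (r2 >= np.asarray(null95))
    valid &= np.isfinite(r2)
    bouts = []
    duration = 0
    i = 0
    n = len(valid)
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            if j - i >= min_run:
                bouts.append((float(window_mid_ms[i]), float(window_mid_ms[j - 1])))
                duration += j - i
            i = j
        else:
            i += 1
    tuned = len(bouts) > 0
    return TuningProfile(
        window_mid_ms=np.asarray(window_mid_ms, dtype=float),
        r2=r2,
        null95=np.asarray(null95, dtype=float),
        bouts=bouts,
        tuned=tuned,
        start_ms=bouts[0][0] if tuned else np.nan,
        finish_ms=bouts[-1][1] if tuned else np.nan,
        duration_ms=duration * BIN_MS,
    )


def dynamic_range(
    psths_by_speed: np.ndarray,
    window_bins: int = WINDOW_BINS,
    step_bins: int = 1,
    grid: TrialGrid = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window firing-rate range across the six speed PSTHs.

    ``psths_by_speed`` is (n_speeds, n_bins) in Hz (all speeds for one
    unit/state).  Returns (window midpoints ms, range Hz), where range is
    the max minus min over speeds of the window-mean rate.
    """
    P = np.asarray(psths_by_speed, dtype=float)
    if P.ndim != 2:
        raise ValueError("expected (n_speeds, n_bins)")
    means = sliding_window_sums(P, window_bins, step_bins, axis=-1) / window_bins
    starts = window_starts(P.shape[1], window_bins, step_bins)
    mids = window_mid_ms(starts, window_bins, grid)
    return mids, means.max(axis=0) - means.min(axis=0)
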