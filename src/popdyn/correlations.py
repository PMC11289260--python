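"""Sliding-window pairwise correlations and their temporal stability.

For each 200 ms window (10 ms step) the *total* pairwise Pearson
correlation of window spike counts across trials is partitioned into a
*signal* part -- estimated by shuffling trial counts within stimulus
conditions (which preserves tuning but destroys trial-by-trial
covariability) -- and a *noise* part, defined elementwise as
total - signal.  The relationship between the two is summarised by the
per-window least-squares slope of noise on signal correlations, and the
temporal stability of the correlation structure by Pearson correlations
between vectorised correlation matrices from different windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import (
    DEFAULT_GRID,
    TrialGrid,
    sliding_window_sums,
    window_mid_ms,
    window_starts,
)

WINDOW_BINS = 20  # 200 ms


@dataclass
class CorrelationTensor:
    """Per-window total/signal/noise correlation matrices for one state."""

    window_mid_ms: np.ndarray  # (W,)
    total: np.ndarray  # (W, P, P)
    signal: np.ndarray  # (W, P, P)
    noise: np.ndarray  # (W, P, P)
    unit_ids: np.ndarray
    state: str | None = None

    def mean_abs(self, flavour: str) -> np.ndarray:
        """Mean absolute off-diagonal correlation per window."""
        M = getattr(self, flavour)
        iu = np.triu_indices(M.shape[1], k=1)
        vals = M[:, iu[0], iu[1]]
        return np.nanmean(np.abs(vals), axis=1)


def _corr_over_trials(X: np.ndarray) -> np.ndarray:
    """Pearson correlations across trials.

    ``X`` is (n_trials, P, W); returns (W, P, P) with NaN where a unit
    has zero variance in a window.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    sd = Xc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = Xc / sd[None, :, :]
    C = np.einsum("tpw,tqw->wpq", np.nan_to_num(Z), np.nan_to_num(Z)) / n
    bad = (~(sd > 0)).T  # (W, P)
    C[bad[:, :, None] | bad[:, None, :]] = np.nan
    idx = np.arange(C.shape[1])
    C[:, idx, idx] = np.where(np.isnan(C[:, idx, idx]), np.nan, 1.0)
    return C


def pairwise_correlations(
    counts: np.ndarray,
    speed_labels: np.ndarray,
    rng: np.random.Generator | int = 0,
    n_shuffles: int = 10,
    window_bins: int = WINDOW_BINS,
    step_bins: int = 1,
    unit_ids: np.ndarray | None = None,
    state: str | None = None,
    grid: TrialGrid = DEFAULT_GRID,
) -> CorrelationTensor:
    """Total/signal/noise correlation tensor from binned counts.

    ``counts`` is (n_trials, n_units, n_bins) for one behavioural state
    (all six stimulus conditions pooled).  The signal estimate averages
    ``n_shuffles`` within-condition trial shuffles, each permuting trials
    independently per unit.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    counts = np.asarray(counts, dtype=float)
    n_trials, P, n_bins = counts.shape
    if P < 2:
        raise ValueError("need >= 2 units")
    labels = np.asarray(speed_labels)
    for lab in np.unique(labels):
        if (labels == lab).sum() < 2:
            raise ValueError(f"need >= 2 trials per condition ({lab!r})")
    W = sliding_window_sums(counts, window_bins, step_bins, axis=-1)
    starts = window_starts(n_bins, window_bins, step_bins)
    mids = window_mid_ms(starts, window_bins, grid)

    total = _corr_over_trials(W)
    signal = np.zeros_like(total)
    groups = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    for _ in range(n_shuffles):
        perm = np.arange(n_trials)[:, None] * np.ones(P, dtype=int)[None, :]
        for idx in groups:
            for p in range(P):
                perm[idx, p] = idx[rng.permutation(len(idx))]
        shuffled = W[perm, np.arange(P)[None, :], :]
        signal += _corr_over_trials(shuffled)
    signal /= n_shuffles
    noise = total - signal
    if unit_ids is None:
        unit_ids = np.arange(P)
    return CorrelationTensor(
        window_mid_ms=mids, total=total, signal=signal, noise=noise,
        unit_ids=np.asarray(unit_ids), state=state,
    )


def signal_noise_slope(tensor: CorrelationTensor) -> np.ndarray:
    """Per-window OLS slope of noise correlations on signal correlations."""
    iu = np.triu_indices(tensor.total.shape[1], k=1)
    x = tensor.signal[:, iu[0], iu[1]]
    y = tensor.noise[:, iu[0], iu[1]]
    W = x.shape[0]
    out = np.full(W, np.nan)
    for w in range(W):
        ok = np.isfinite(x[w]) & np.isfinite(y[w])
        if ok.sum() < 3:
            continue
        xv, yv = x[w, ok], y[w, ok]
        vx = np.var(xv)
        if vx == 0:
            continue
        out[w] = float(np.cov(xv, yv, ddof=0)[0, 1] / vx)
    return out


def correlation_ordering(tensor: CorrelationTensor, anchor_ms: float = 800.0,
                         flavour: str = "total") -> np.ndarray:
    """Display ordering of units by hierarchical clustering.

    Cosmetic: clusters units on 1 - correlation at the window whose
    midpoint is nearest ``anchor_ms`` (unweighted average linkage) so
    the same ordering can be applied to every window's matrix.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    w = int(np.argmin(np.abs(tensor.window_mid_ms - anchor_ms)))
    M = np.nan_to_num(getattr(tensor, flavour)[w], nan=0.0)
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    return leaves_list(linkage(squareform(D, checks=False), method="average"))


@dataclass
class StabilityMatrix:
    window_mid_ms: np.ndarray
    matrix: np.ndarray  # (W, W)
    flavour: str

    def neighbour_diagonal(self, lag: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Stability between non-overlapping neighbouring windows.

        Returns (midpoint between the two windows in ms, values) along
        the ``lag``-th diagonal (lag 20 steps = 200 ms, i.e. adjacent
        non-overlapping 200 ms windows).
        """
        W = self.matrix.shape[0]
        if lag >= W:
            return np.array([]), np.array([])
        vals = np.array([self.matrix[i, i + lag] for i in range(W - lag)])
        mids = 0.5 * (self.window_mid_ms[:-lag] + self.window_mid_ms[lag:])
        return mids, vals


def structure_stability(
    matrices: np.ndarray,
    window_mid_ms: np.ndarray,
    flavour: str = "signal",
) -> StabilityMatrix:
    """T x T Pearson correlations between per-window correlation matrices.

    Each window's matrix is vectorised over the upper off-diagonal
    triangle (row-major); missing pairs are excluded pairwise-complete.
    """
    M = np.asarray(matrices, dtype=float)
    W = M.shape[0]
    if W < 2:
        raise ValueError("need >= 2 windows")
    iu = np.triu_indices(M.shape[1], k=1)
    V = M[:, iu[0], iu[1]]  # (W, n_pairs)
    out = np.full((W, W), np.nan)
    for i in range(W):
        out[i, i] = 1.0 if np.isfinite(V[i]).any() else np.nan
        for j in range(i + 1, W):
            ok = np.isfinite(V[i]) & np.isfinite(V[j])
            if ok.sum() < 3:
                continue
            a, b = V[i, ok], V[j, ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = float(((a - a.mean()) @ (b - b.mean())) / (len(a) * sa * sb))
            out[i, j] = out[j, i] = r
    return StabilityMatrix(window_mid_ms=np.asarray(window_mid_ms),
                           matrix=out, flavour=flavour)
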