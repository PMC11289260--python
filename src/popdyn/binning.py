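"""Trial time base, spike binning and sliding-window helpers.

Every stage of the pipeline works on spike counts in 10 ms bins over a
peri-stimulus window running from 200 ms before stimulus onset to 800 ms
after stimulus offset (2000 ms total for a 1 s stimulus).  Sliding-window
statistics (tuning, correlations, decoding) are computed on sums of these
bins, so the helpers here are the single source of truth for bin edges,
bin centres and window midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BIN_MS: float = 10.0
"""Width of the elementary analysis bin in milliseconds."""


@dataclass(frozen=True)
class TrialGrid:
    """Peri-stimulus time grid in 10 ms bins.

    Parameters
    ----------
    pre_ms : float
        Time before stimulus onset included in the window.
    stim_ms : float
        Stimulus duration (onset at t=0, offset at t=stim_ms).
    post_ms : float
        Time after stimulus offset included in the window.
    """

    pre_ms: float = 200.0
    stim_ms: float = 1000.0
    post_ms: float = 800.0

    @property
    def start_ms(self) -> float:
        return -self.pre_ms

    @property
    def stop_ms(self) -> float:
        return self.stim_ms + self.post_ms

    @property
    def n_bins(self) -> int:
        return int(round((self.stop_ms - self.start_ms) / BIN_MS))

    @property
    def edges_ms(self) -> np.ndarray:
        return self.start_ms + BIN_MS * np.arange(self.n_bins + 1)

    @property
    def centers_ms(self) -> np.ndarray:
        return self.start_ms + BIN_MS * (np.arange(self.n_bins) + 0.5)

    def bin_of(self, t_ms: float) -> int:
        """Index of the bin whose left edge is at ``t_ms``."""
        idx = (t_ms - self.start_ms) / BIN_MS
        out = int(round(idx))
        if not np.isclose(idx, out):
            raise ValueError(f"{t_ms} ms is not on the {BIN_MS} ms bin grid")
        return out

    def slice_ms(self, t0_ms: float, t1_ms: float) -> slice:
        """Bin slice covering [t0_ms, t1_ms)."""
        return slice(self.bin_of(t0_ms), self.bin_of(t1_ms))


DEFAULT_GRID = TrialGrid()


def bin_spikes(
    spike_times_s: np.ndarray,
    onsets_s: np.ndarray,
    grid: TrialGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Bin one unit's spike times around each trial onset.

    Parameters
    ----------
    spike_times_s : array
        Sorted spike times in seconds.
    onsets_s : array
        Trial onset times in seconds.

    Returns
    -------
    counts : int array, shape (n_trials, n_bins)
    """
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    onsets_s = np.asarray(onsets_s, dtype=float)
    edges_s = grid.edges_ms / 1000.0
    query = onsets_s[:, None] + edges_s[None, :]
    idx = np.searchsorted(spike_times_s, query.ravel()).reshape(query.shape)
    return np.diff(idx, axis=1)


def window_starts(n_bins: int, window_bins: int, step_bins: int = 1) -> np.ndarray:
    """Start bin indices of sliding windows fully contained in the grid.

    Windows that would be truncated at either edge are dropped rather than
    padded.
    """
    last = n_bins - window_bins
    if last < 0:
        return np.array([], dtype=int)
    return np.arange(0, last + 1, step_bins)


def window_mid_ms(
    starts: np.ndarray, window_bins: int, grid: TrialGrid = DEFAULT_GRID
) -> np.ndarray:
    """Window midpoints in milliseconds relative to stimulus onset."""
    return grid.start_ms + BIN_MS * (np.asarray(starts) + window_bins / 2.0)


def sliding_window_sums(
    counts: np.ndarray, window_bins: int, step_bins: int = 1, axis: int = -1
) -> np.ndarray:
    """Sums of ``counts`` in sliding windows along ``axis``.

    Implemented with a cumulative sum so the cost is independent of the
    window size.
    """
    counts = np.moveaxis(np.asarray(counts), axis, -1)
    cs = np.concatenate(
        [np.zeros(counts.shape[:-1] + (1,), dtype=float), np.cumsum(counts, axis=-1)],
        axis=-1,
    )
    starts = window_starts(counts.shape[-1], window_bins, step_bins)
    out = cs[..., starts + window_bins] - cs[..., starts]
    return np.moveaxis(out, -1, axis)
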