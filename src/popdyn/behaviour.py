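"""Behavioural-state processing and trial classification.

Wheel (rotary-encoder) traces are converted to smoothed locomotion speed,
trials are classified as stationary / locomotion under three criteria
sets ("main", "stricter", "changepoints"), stationary trials can be
partitioned by pupil-area tertiles (arousal) and locomotion trials by
speed quartiles, and trial counts are balanced across the 12 stimulus x
state conditions.

All per-trial statistics are evaluated on the 10 ms trace bins whose
centres fall inside the 2000 ms trial window (200 ms pre-onset to 800 ms
post-offset).  Fractions like ">75% of the window" use strict
inequalities at the bin level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import BIN_MS, DEFAULT_GRID, TrialGrid
from .smoothing import gaussian_smooth

CRITERIA_SETS = ("main", "stricter", "changepoints")


def compute_speed(
    tick_counts: np.ndarray,
    sample_times_s: np.ndarray,
    wheel_radius_cm: float,
    ticks_per_revolution: int = 1024,
    smooth_sd_ms: float = 35.0,
) -> pd.DataFrame:
    """Convert cumulative encoder ticks to a smoothed speed trace.

    Ticks are converted to linear distance from the wheel radius, the
    temporal derivative is taken at the native (60 Hz) sampling rate, the
    result is resampled onto 10 ms bins and smoothed with a Gaussian
    kernel (SD 35 ms).

    Returns a DataFrame with columns ``time_s`` and ``speed_cm_s``.
    """
    tick_counts = np.asarray(tick_counts, dtype=float)
    sample_times_s = np.asarray(sample_times_s, dtype=float)
    if np.any(np.diff(sample_times_s) <= 0):
        raise ValueError("sample times must be strictly increasing")
    dist_cm = tick_counts / ticks_per_revolution * 2.0 * np.pi * wheel_radius_cm
    v_native = np.diff(dist_cm) / np.diff(sample_times_s)
    t_native = 0.5 * (sample_times_s[:-1] + sample_times_s[1:])
    dt = BIN_MS / 1000.0
    t_grid = np.arange(sample_times_s[0], sample_times_s[-1], dt) + dt / 2.0
    v_grid = np.interp(t_grid, t_native, v_native)
    v_smooth = gaussian_smooth(v_grid, sd_ms=smooth_sd_ms)
    return pd.DataFrame({"time_s": t_grid, "speed_cm_s": v_smooth})


def _trial_bins(trace_t: np.ndarray, onset_s: float, grid: TrialGrid) -> slice:
    t0 = onset_s + grid.start_ms / 1000.0
    t1 = onset_s + grid.stop_ms / 1000.0
    i0 = int(np.searchsorted(trace_t, t0))
    i1 = int(np.searchsorted(trace_t, t1))
    return slice(i0, i1)


def _locomotion_epochs(
    speed: np.ndarray,
    time_s: np.ndarray,
    z_threshold: float = 0.05,
    min_mean_cm_s: float = 3.0,
    min_duration_s: float = 5.0,
    shrink_s: float = 0.5,
    smooth_sd_ms: float = 400.0,
):
    """Changepoints-style locomotion epochs.

    Speed is z-scored over the whole session, smoothed with a 400 ms SD
    Gaussian, and epochs are opened/closed where the processed trace
    crosses ``z_threshold``.  Epochs with mean raw speed < 3 cm/s or
    duration < 5 s are dropped, and survivors are shrunk by 0.5 s at both
    ends.  Returns ``(initial_epochs, surviving_epochs)`` as lists of
    ``(t_on, t_off)`` tuples.

    A constant trace has zero variance; in that degenerate case the whole
    session is one epoch if its speed exceeds the 3 cm/s mean criterion,
    otherwise there are no epochs.
    """
    sd = speed.std()
    if sd == 0:
        if speed.mean() > min_mean_cm_s:
            initial = [(time_s[0], time_s[-1])]
        else:
            initial = []
        surviving = [
            (a + shrink_s, b - shrink_s)
            for a, b in initial
            if (b - shrink_s) - (a + shrink_s) > 0
        ]
        return initial, surviving
    z = (speed - speed.mean()) / sd
    zs = gaussian_smooth(z, sd_ms=smooth_sd_ms)
    above = zs > z_threshold
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        stops = stops + [len(above)]
    initial = [(time_s[a], time_s[b - 1]) for a, b in zip(starts, stops)]
    surviving = []
    for (a_idx, b_idx), (ta, tb) in zip(zip(starts, stops), initial):
        if tb - ta < min_duration_s:
            continue
        if speed[a_idx:b_idx].mean() < min_mean_cm_s:
            continue
        ta2, tb2 = ta + shrink_s, tb - shrink_s
        if tb2 > ta2:
            surviving.append((ta2, tb2))
    return initial, surviving


def classify_trials(
    trace: pd.DataFrame,
    trials: pd.DataFrame,
    criteria: str = "main",
    grid: TrialGrid = DEFAULT_GRID,
) -> pd.DataFrame:
    """Label every trial stationary / locomotion / excluded.

    ``trace`` must have columns ``time_s`` and ``speed_cm_s`` on a
    uniform 10 ms grid covering every trial window.

    Criteria sets:

    * ``main`` -- stationary iff mean speed < 0.5 cm/s AND speed < 3 cm/s
      for > 75% of the window; locomotion iff mean > 3 cm/s AND
      speed > 0.5 cm/s for > 75%.
    * ``stricter`` -- stationary iff speed < 0.5 cm/s throughout;
      locomotion iff mean > 3 cm/s AND speed > 0.5 cm/s for >= 90%.
    * ``changepoints`` -- locomotion iff the full window lies inside a
      surviving locomotion epoch; stationary iff the window intersects no
      initial epoch; excluded otherwise.
    """
    if criteria not in CRITERIA_SETS:
        raise ValueError(f"unknown criteria set {criteria!r}")
    t = trace["time_s"].to_numpy(dtype=float)
    v = trace["speed_cm_s"].to_numpy(dtype=float)
    if criteria == "changepoints":
        initial, surviving = _locomotion_epochs(v, t)

    labels = []
    for row in trials.itertuples():
        sl = _trial_bins(t, row.onset_s, grid)
        seg = v[sl]
        if len(seg) < grid.n_bins:
            raise ValueError(
                f"behaviour trace does not cover trial {row.trial_id} "
                f"(onset {row.onset_s} s)"
            )
        if criteria == "main":
            if seg.mean() < 0.5 and np.mean(seg < 3.0) > 0.75:
                lab = "stationary"
            elif seg.mean() > 3.0 and np.mean(seg > 0.5) > 0.75:
                lab = "locomotion"
            else:
                lab = "excluded"
        elif criteria == "stricter":
            if np.all(seg < 0.5):
                lab = "stationary"
            elif seg.mean() > 3.0 and np.mean(seg > 0.5) >= 0.90:
                lab = "locomotion"
            else:
                lab = "excluded"
        else:  # changepoints
            w0 = row.onset_s + grid.start_ms / 1000.0
            w1 = row.onset_s + grid.stop_ms / 1000.0
            if any(a <= w0 and w1 <= b for a, b in surviving):
                lab = "locomotion"
            elif not any(a < w1 and w0 < b for a, b in initial):
                lab = "stationary"
            else:
                lab = "excluded"
        labels.append(lab)
    return pd.DataFrame(
        {
            "trial_id": trials["trial_id"].to_numpy(),
            "state": labels,
            "criteria": criteria,
        }
    )


def _window_means(
    trace: pd.DataFrame,
    value_col: str,
    trials: pd.DataFrame,
    t0_ms: float,
    t1_ms: float,
) -> np.ndarray:
    t = trace["time_s"].to_numpy(dtype=float)
    x = trace[value_col].to_numpy(dtype=float)
    out = np.empty(len(trials))
    for i, row in enumerate(trials.itertuples()):
        i0 = int(np.searchsorted(t, row.onset_s + t0_ms / 1000.0))
        i1 = int(np.searchsorted(t, row.onset_s + t1_ms / 1000.0))
        out[i] = x[i0:i1].mean()
    return out


def partition_trials(
    trace: pd.DataFrame,
    trials: pd.DataFrame,
    mode: str,
    grid: TrialGrid = DEFAULT_GRID,
) -> pd.DataFrame:
    """Partition trials by arousal (pupil tertiles) or running speed.

    ``pupil_tertiles`` expects stationary trials and a trace with an
    ``area_au`` column: per-trial stimulus-period mean pupil area is
    split at its tertiles; the bottom third is "low" arousal, the top
    third "high", and the middle third dropped.  ``speed_quartiles``
    expects locomotion trials and a ``speed_cm_s`` column: the slowest
    25% are "slow", the fastest 25% "fast".  Values equal to a boundary
    go to the lower group.
    """
    if len(trials) < 4:
        raise ValueError("need at least 4 trials to partition")
    if mode == "pupil_tertiles":
        if "area_au" not in trace.columns:
            raise ValueError("pupil partition requires an 'area_au' trace")
        vals = _window_means(trace, "area_au", trials, 0.0, grid.stim_ms)
        t1, t2 = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0])
        label = np.where(vals <= t1, "low", np.where(vals > t2, "high", "dropped"))
    elif mode == "speed_quartiles":
        vals = _window_means(trace, "speed_cm_s", trials, 0.0, grid.stim_ms)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        label = np.where(vals <= q1, "slow", np.where(vals > q3, "fast", "dropped"))
    else:
        raise ValueError(f"unknown partition mode {mode!r}")
    return pd.DataFrame(
        {"trial_id": trials["trial_id"].to_numpy(), "value": vals, "label": label}
    )


def balance_conditions(
    state_table: pd.DataFrame,
    trials: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Downsample so all 12 speed x state conditions have equal counts.

    Only trials labelled stationary or locomotion with a non-blank speed
    are considered.  Returns the balanced subset of the trial table
    (merged with state labels), subsampled uniformly at random with the
    given seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    merged = trials.merge(state_table[["trial_id", "state"]], on="trial_id")
    merged = merged[
        merged["state"].isin(["stationary", "locomotion"])
        & merged["speed_deg_s"].notna()
    ]
    groups = merged.groupby(["state", "speed_deg_s"], sort=True)
    speeds = np.sort(merged["speed_deg_s"].unique())
    expected = [(s, v) for s in ("stationary", "locomotion") for v in speeds]
    missing = [key for key in expected if key not in groups.groups]
    if missing or len(speeds) == 0:
        raise ValueError(f"empty conditions: {missing or 'no stimulus trials'}")
    n_min = groups.size().min()
    keep = []
    for _, g in groups:
        ids = g["trial_id"].to_numpy()
        keep.append(np.sort(rng.choice(ids, size=n_min, replace=False)))
    keep = np.sort(np.concatenate(keep))
    return merged[merged["trial_id"].isin(keep)].reset_index(drop=True)
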