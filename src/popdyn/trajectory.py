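"""Geometric and kinematic metrics of latent population trajectories.

All metrics act on an (m, T) trajectory on the 10 ms trial grid.
Epochs: the *onset* transition runs from stimulus onset (t = 0) to the
stimulus steady state (500-1000 ms); the *offset* transition from
stimulus offset (t = 1000 ms) to the post-stimulus steady state
(1500-1800 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .binning import BIN_MS, DEFAULT_GRID, TrialGrid, sliding_window_sums, \
    window_mid_ms, window_starts

EPOCH_DEFS = {
    # epoch -> (T_start ms, steady-state window ms)
    "onset": (0.0, (500.0, 1000.0)),
    "offset": (1000.0, (1500.0, 1800.0)),
}
ANGLE_WINDOWS = {
    # epoch -> (initial steady window ms, final steady window ms)
    "onset": ((-200.0, 0.0), (500.0, 1000.0)),
    "offset": ((500.0, 1000.0), (1500.0, 1800.0)),
}


@dataclass
class PathMetrics:
    epoch: str
    cumulative_distance: float
    direct_distance: float
    distance_ratio: float
    ss_size: float
    t_start_ms: float
    t_end_ms: float
    t_end_capped: bool


def path_metrics(
    traj: np.ndarray,
    epoch: str = "onset",
    grid: TrialGrid = DEFAULT_GRID,
    window_bins: int = 20,
    min_run: int = 10,
) -> PathMetrics:
    """Cumulative/direct distance and distance ratio between steady states.

    The steady-state size is the maximal distance of the trajectory from
    the steady-state centre over the steady window.  The arrival time
    ``T_end`` is the midpoint of the first window of the first run of
    >= 10 consecutive 200 ms sliding windows (10 ms step) whose mean
    distance to the centre is below that size, capped at the start of
    the steady window.  The distance ratio (cumulative / direct) is >= 1
    and equals 1 only for a straight monotone path.
    """
    if epoch not in EPOCH_DEFS:
        raise ValueError(f"unknown epoch {epoch!r}")
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    t_start_ms, (ss0, ss1) = EPOCH_DEFS[epoch]
    centers = grid.centers_ms
    steady = grid.slice_ms(ss0, ss1)
    xbar = traj[:, steady].mean(axis=1)
    dist = np.linalg.norm(traj - xbar[:, None], axis=0)
    ss_size = float(dist[steady].max())

    # windowed distance-to-centre, restricted to windows starting at/after
    # the transition start
    wdist = sliding_window_sums(dist, window_bins, 1) / window_bins
    starts = window_starts(len(dist), window_bins, 1)
    mids = window_mid_ms(starts, window_bins, grid)
    i0 = int(np.searchsorted(mids, t_start_ms))
    inside = wdist < ss_size
    t_end_ms = None
    run = 0
    for i in range(i0, len(inside)):
        run = run + 1 if inside[i] else 0
        if run >= min_run:
            t_end_ms = float(mids[i - min_run + 1])
            break
    capped = t_end_ms is None or t_end_ms > ss0
    if capped:
        t_end_ms = ss0

    sel = (centers >= t_start_ms) & (centers <= t_end_ms)
    if sel.sum() < 2:  # immediate arrival: keep a minimal 2-bin segment
        i0_bin = int(np.searchsorted(centers, t_start_ms))
        sel = np.zeros_like(sel)
        sel[i0_bin : i0_bin + 2] = True
    seg = traj[:, sel]
    steps = np.linalg.norm(np.diff(seg, axis=1), axis=0)
    cum = float(steps.sum())
    direct = float(np.linalg.norm(seg[:, -1] - seg[:, 0]))
    ratio = cum / direct if direct > 0 else np.nan
    return PathMetrics(
        epoch=epoch, cumulative_distance=cum, direct_distance=direct,
        distance_ratio=ratio, ss_size=ss_size, t_start_ms=t_start_ms,
        t_end_ms=t_end_ms, t_end_capped=capped,
    )


@dataclass
class Kinematics:
    time_ms: np.ndarray  # times of the speed samples
    speed: np.ndarray  # per-factor-normalised speed
    acceleration: np.ndarray
    max_speed: float
    freq_hz: np.ndarray
    relative_power: np.ndarray  # acceleration spectrum / band mean
    low_band_fraction: float  # share of 0-6 Hz power in the 0-20 Hz band


def kinematics(
    traj: np.ndarray,
    grid: TrialGrid = DEFAULT_GRID,
    band_hz: tuple = (0.0, 20.0),
    low_hz: float = 6.0,
) -> Kinematics:
    """Trajectory speed, acceleration and acceleration power spectrum.

    Speed is the backward-difference path speed divided by the number of
    latent factors; acceleration is its time derivative.  The spectrum
    of the acceleration series is reported on 0-20 Hz relative to its
    band mean.
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    m, T = traj.shape
    if m == 0:
        raise ValueError("empty trajectory")
    dt = BIN_MS / 1000.0
    speed = np.linalg.norm(np.diff(traj, axis=1), axis=0) / dt / m
    accel = np.diff(speed) / dt
    f, pxx = periodogram(accel, fs=1000.0 / BIN_MS)
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    f, pxx = f[sel], pxx[sel]
    mean_p = pxx.mean() if pxx.size else np.nan
    rel = pxx / mean_p if mean_p and mean_p > 0 else np.full_like(pxx, np.nan)
    total = pxx.sum()
    low = float(pxx[f <= low_hz].sum() / total) if total > 0 else np.nan
    return Kinematics(
        time_ms=grid.centers_ms[1:],
        speed=speed,
        acceleration=accel,
        max_speed=float(speed.max()),
        freq_hz=f,
        relative_power=rel,
        low_band_fraction=low,
    )


@dataclass
class AngleOfApproach:
    time_ms: np.ndarray
    theta_deg: np.ndarray
    cumulative_deviation_deg: float


def angle_of_approach(
    traj: np.ndarray,
    epoch: str = "onset",
    grid: TrialGrid = DEFAULT_GRID,
    until_arrival: bool = True,
) -> AngleOfApproach:
    """Angle between the approach direction and the direct path.

    The reference vector joins the mean positions in the initial and
    final steady windows; theta(t) is the angle between it and the
    vector from the trajectory to the final steady centre.  Where the
    trajectory sits exactly at the centre the angle is undefined and the
    previous value is carried forward.  The cumulative angular deviation
    sums |theta(t+1) - theta(t)| over the transition, from the epoch
    start to the steady-state arrival time (the same arrival rule as the
    distance measures) when ``until_arrival`` is set, otherwise to the
    start of the final steady window.  Once the trajectory sits at the
    steady state |b(t)| shrinks towards zero and the angle becomes
    ill-conditioned, so extending the sum past arrival accumulates
    estimation noise rather than path geometry.
    """
    if epoch not in ANGLE_WINDOWS:
        raise ValueError(f"unknown epoch {epoch!r}")
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    (i0, i1), (f0, f1) = ANGLE_WINDOWS[epoch]
    x_init = traj[:, grid.slice_ms(i0, i1)].mean(axis=1)
    x_fin = traj[:, grid.slice_ms(f0, f1)].mean(axis=1)
    a = x_fin - x_init
    b = x_fin[:, None] - traj
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (a @ b) / (na * nb)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta[nb == 0] = np.nan
    # carry last defined value forward
    for i in range(1, len(theta)):
        if np.isnan(theta[i]):
            theta[i] = theta[i - 1]
    t_lo = 0.0 if epoch == "onset" else 1000.0
    t_hi = f0
    if until_arrival:
        t_hi = min(t_hi, path_metrics(traj, epoch, grid=grid).t_end_ms)
    sel = grid.slice_ms(t_lo, max(t_hi, t_lo + 20.0))
    seg = theta[sel]
    dev = float(np.nansum(np.abs(np.diff(seg))))
    return AngleOfApproach(time_ms=grid.centers_ms, theta_deg=theta,
                           cumulative_deviation_deg=dev)


def tangling_epsilon(trajs, eps_scale: float = 0.1) -> float:
    """Shared tangling constant for a set of trajectories.

    ``eps_scale`` times the mean squared distance of all trajectory
    points from their grand mean, pooled over the set.  Using one
    constant across conditions/states keeps their tangling values on a
    common scale; a per-trajectory constant would renormalise away
    genuine scale differences between conditions.
    """
    A = np.concatenate([np.atleast_2d(t) for t in trajs], axis=1)
    Ac = A - A.mean(axis=1, keepdims=True)
    return eps_scale * float((Ac**2).sum(axis=0).mean())


def tangling(
    traj: np.ndarray,
    window_ms: float = 200.0,
    eps: float | None = None,
    eps_scale: float = 0.1,
    grid: TrialGrid = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-trajectory tangling Q(t).

    Q(t) is the 90th percentile over nearby timepoints t' (within
    +/-100 ms, t' != t) of ||xdot_t - xdot_t'||^2 / (||x_t - x_t'||^2 +
    eps).  Velocity uses the backward first difference (the first sample
    has no velocity and is excluded).  When ``eps`` is not given it is
    set to ``eps_scale`` times the mean squared distance of the
    trajectory from its grand mean -- a scale-proportional constant, so
    tangling is invariant to translation and comparably scaled across
    sessions.

    Returns (time_ms, Q) aligned with the velocity samples; entries with
    fewer than two comparison points are NaN.
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    dt = BIN_MS / 1000.0
    x = traj[:, 1:]  # positions with defined velocity
    v = np.diff(traj, axis=1) / dt
    T = x.shape[1]
    if eps is None:
        xc = traj - traj.mean(axis=1, keepdims=True)
        eps = eps_scale * float((xc**2).sum(axis=0).mean())
    half = int(round(window_ms / 2.0 / BIN_MS))
    Q = np.full(T, np.nan)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        idx = [i for i in range(lo, hi) if i != t]
        if len(idx) < 2:
            continue
        dv = v[:, idx] - v[:, [t]]
        dx = x[:, idx] - x[:, [t]]
        ratio = (dv**2).sum(axis=0) / ((dx**2).sum(axis=0) + eps)
        Q[t] = np.percentile(ratio, 90.0)
    return grid.centers_ms[1:], Q


def procrustes_similarity(X: np.ndarray, Y: np.ndarray) -> float:
    """Similarity-transform shape match between two point sets.

    Finds the translation, orthogonal rotation/reflection and isotropic
    scaling of ``Y`` (T x d) minimising the squared distance to ``X``;
    the dissimilarity d = min SSE / scale(X) (scale = sum of squared
    elements of centred X) lies in [0, 1] and 1 - d is returned, so a
    perfect match under any similarity transform scores 1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("X and Y must have the same shape")
    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)
    ssX = float((X0**2).sum())
    ssY = float((Y0**2).sum())
    if ssX == 0:
        return np.nan
    if ssY == 0:
        return 0.0
    s = np.linalg.svd(Y0.T @ X0, compute_uv=False)
    d = 1.0 - (s.sum() ** 2) / (ssX * ssY)
    return float(1.0 - d)


def inter_trajectory_distance(trajs: dict) -> np.ndarray:
    """Mean pairwise Euclidean distance between per-speed trajectories.

    ``trajs`` maps each stimulus speed to an (m, T) trial-averaged
    trajectory; the result is the per-timepoint mean over all unordered
    speed pairs.
    """
    keys = sorted(trajs)
    if len(keys) < 2:
        raise ValueError("need at least two trajectories")
    A = np.stack([np.atleast_2d(trajs[k]) for k in keys])  # (K, m, T)
    K = len(keys)
    acc = 0.0
    n_pairs = 0
    for i in range(K):
        for j in range(i + 1, K):
            acc = acc + np.linalg.norm(A[i] - A[j], axis=0)
            n_pairs += 1
    return acc / n_pairs
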