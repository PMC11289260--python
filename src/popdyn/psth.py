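"""Single-neuron PSTH characterisation.

Builds trial-averaged smoothed firing-rate profiles (PSTHs), assesses
their reliability with three criteria, classifies onset/offset response
features with constrained Gaussian descriptive fits, computes a
sustainedness index, sorts responses with DTW-based hierarchical
clustering, and filters/types units from their quality metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.spatial.distance import squareform

from .binning import BIN_MS, DEFAULT_GRID, TrialGrid
from .smoothing import DEFAULT_SMOOTH_SD_MS, gaussian_smooth, smoothing_matrix

FEATURES = ("Decay", "Rise", "Peak", "Trough", "Flat")
EPOCHS = {"onset": (0.0, 300.0), "offset": (1000.0, 1500.0)}


@dataclass
class Psth:
    """Trial-averaged smoothed firing-rate profile for one condition."""

    rate_hz: np.ndarray  # (n_bins,)
    unit_id: object = None
    speed: float | None = None
    state: str | None = None
    n_trials: int = 0
    baseline_mean_hz: float = np.nan
    baseline_sd_hz: float = np.nan
    smooth_sd_ms: float = DEFAULT_SMOOTH_SD_MS
    grid: TrialGrid = field(default_factory=TrialGrid)

    @property
    def range_hz(self) -> float:
        return float(self.rate_hz.max() - self.rate_hz.min())

    def normalised(self) -> np.ndarray:
        """Whole-profile min-max normalisation to [0, 1]."""
        lo, hi = self.rate_hz.min(), self.rate_hz.max()
        if hi == lo:
            return np.zeros_like(self.rate_hz)
        return (self.rate_hz - lo) / (hi - lo)


def build_psth(
    trial_counts: np.ndarray,
    smooth_sd_ms: float = DEFAULT_SMOOTH_SD_MS,
    bin_ms: float = BIN_MS,
    **meta,
) -> Psth:
    """PSTH from per-trial binned spike counts.

    ``trial_counts`` has shape (n_trials, n_bins); counts are averaged
    over trials, scaled to Hz and smoothed (Gaussian SD 35 ms).
    """
    trial_counts = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    if trial_counts.shape[0] == 0:
        raise ValueError("no trials in condition")
    rate = gaussian_smooth(
        trial_counts.mean(axis=0) * (1000.0 / bin_ms), sd_ms=smooth_sd_ms,
        bin_ms=bin_ms,
    )
    return Psth(rate_hz=rate, n_trials=trial_counts.shape[0],
                smooth_sd_ms=smooth_sd_ms, **meta)


def baseline_stats(
    blank_counts: np.ndarray,
    smooth_sd_ms: float = DEFAULT_SMOOTH_SD_MS,
    bin_ms: float = BIN_MS,
) -> tuple[float, float]:
    """Mean and SD of firing rate over blank (no-stimulus) trials.

    Single-trial binned rates are smoothed like PSTHs and pooled over
    trials and bins.
    """
    blank_counts = np.atleast_2d(np.asarray(blank_counts, dtype=float))
    if blank_counts.shape[0] == 0:
        raise ValueError("no blank trials available")
    rates = gaussian_smooth(blank_counts * (1000.0 / bin_ms), sd_ms=smooth_sd_ms,
                            bin_ms=bin_ms, axis=-1)
    return float(rates.mean()), float(rates.std())


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityResult:
    range_hz: float
    max_abs_z: float
    shape_z: float
    range_ok: bool
    z_ok: bool
    shape_ok: bool

    @property
    def reliable(self) -> bool:
        return self.range_ok and self.z_ok and self.shape_ok


def assess_reliability(
    trial_counts: np.ndarray,
    blank_counts: np.ndarray,
    rng: np.random.Generator | int = 0,
    n_splits: int = 25,
    n_shuffles: int = 40,
    smooth_sd_ms: float = DEFAULT_SMOOTH_SD_MS,
    grid: TrialGrid = DEFAULT_GRID,
) -> ReliabilityResult:
    """Three-criterion PSTH reliability test.

    1. Firing-rate range of the PSTH >= 3 Hz.
    2. Max |z| of the PSTH >= 3.29, where per-bin z-scores use the mean
       and SD of smoothed single-trial rates over blank trials.
    3. Shape reliability: over ``n_splits`` random half-splits of the
       trials, the Pearson correlation between the two half-PSTHs (from
       stimulus onset onwards) is compared with a null built by
       uniformly redistributing each trial's spikes over the window
       (``n_shuffles`` surrogates per split).  The shape criterion
       passes if the mean observed correlation exceeds the null at
       one-sided p <= 0.05 (z >= 1.645).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    trial_counts = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    blank_counts = np.atleast_2d(np.asarray(blank_counts, dtype=float))
    if blank_counts.shape[0] == 0:
        raise ValueError("criterion 2 needs blank trials for baseline statistics")
    n_trials, n_bins = trial_counts.shape
    if n_trials < 8:
        raise ValueError("need >= 8 trials to assess reliability")
    hz = 1000.0 / BIN_MS
    S = smoothing_matrix(n_bins, sd_ms=smooth_sd_ms)

    psth = (trial_counts.mean(axis=0) * hz) @ S
    rng_hz = float(psth.max() - psth.min())

    blank_rates = (blank_counts * hz) @ S
    mu_b = blank_rates.mean(axis=0)
    sd_b = blank_rates.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_b > 0, (psth - mu_b) / sd_b, np.where(psth == mu_b, 0.0, np.inf))
    max_abs_z = float(np.nanmax(np.abs(z)))

    # criterion 3 on the window from stimulus onset to the end of the grid
    post = grid.bin_of(0.0)
    half = n_trials // 2
    obs = np.empty(n_splits)
    null = np.empty((n_splits, n_shuffles))
    totals = trial_counts.sum(axis=1).astype(int)
    for i in range(n_splits):
        perm = rng.permutation(n_trials)
        a, b = perm[:half], perm[half : 2 * half]
        pa = (trial_counts[a].mean(axis=0) * hz) @ S
        pb = (trial_counts[b].mean(axis=0) * hz) @ S
        obs[i] = _pearson(pa[post:], pb[post:])
        # surrogate for half b: per-trial spike counts spread uniformly
        tot_b = int(totals[b].sum())
        surro = rng.multinomial(tot_b, np.full(n_bins, 1.0 / n_bins),
                                size=n_shuffles) / max(len(b), 1)
        pb_null = (surro * hz) @ S
        null[i] = _pearson_rows(pb_null[:, post:], pa[post:])
    null = null.ravel()
    nsd = null.std()
    shape_z = float((obs.mean() - null.mean()) / nsd) if nsd > 0 else np.inf
    return ReliabilityResult(
        range_hz=rng_hz,
        max_abs_z=max_abs_z,
        shape_z=shape_z,
        range_ok=rng_hz >= 3.0,
        z_ok=max_abs_z >= 3.29,
        shape_ok=shape_z >= 1.645,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    d = np.sqrt((x @ x) * (y @ y))
    return float(x @ y / d) if d > 0 else 0.0


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    den = np.sqrt((Xc * Xc).sum(axis=1) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / den
    return np.where(den > 0, r, 0.0)


# ---------------------------------------------------------------------------
# descriptive feature fits
# ---------------------------------------------------------------------------


@dataclass
class FeatureFit:
    epoch: str
    label: str
    params: dict  # winning candidate parameters {b, a, u, sigma}
    sse: dict  # candidate -> residual sum of squares


def _gauss(x, b, a, u, sigma):
    return b + a * np.exp(-((x - u) ** 2) / (2.0 * sigma**2))


def _candidate_boxes(E: int) -> dict:
    """Parameter boxes (lo, hi) for (b, a, u, sigma) per candidate shape.

    Decay and Rise each get two parameterisations (positive Gaussian
    centred off one end of the epoch, or its negative mirror); Peak and
    Trough need an interior mean and a narrow sigma so the extremum is
    well defined; Flat is pinned by a near-zero amplitude.
    """
    return {
        "Decay": [
            ((-0.5, 0.0, -E / 2.0, 2.0), (1.5, 1.5, 0.0, 2.0 * E)),
            ((-0.5, -1.5, E, 2.0), (1.5, 0.0, 1.5 * E, 2.0 * E)),
        ],
        "Rise": [
            ((-0.5, 0.0, E, 2.0), (1.5, 1.5, 1.5 * E, 2.0 * E)),
            ((-0.5, -1.5, -E / 2.0, 2.0), (1.5, 0.0, 0.0, 2.0 * E)),
        ],
        "Peak": [((-0.5, 0.0, 0.1 * E, 2.0), (1.5, 1.5, 0.9 * E, E / 3.0))],
        "Trough": [((-0.5, -1.5, 0.1 * E, 2.0), (1.5, 0.0, 0.9 * E, E / 3.0))],
        "Flat": [((-0.5, -0.05, 0.0, 2.0), (1.5, 0.05, float(E), 2.0 * E))],
    }


_PRECEDENCE = {"Flat": 0, "Decay": 1, "Rise": 1, "Peak": 2, "Trough": 2}


def _fit_candidate(x, y, lo, hi, n_starts: int = 5):
    best = None
    u_starts = np.linspace(lo[2], hi[2], n_starts)
    y0 = float(np.clip(y.mean(), lo[0], hi[0]))
    a0 = float(np.clip(y.max() - y.min(), lo[1] + 1e-6, hi[1] - 1e-6)) \
        if hi[1] > 0 else float(np.clip(-(y.max() - y.min()), lo[1] + 1e-6,
                                        hi[1] - 1e-6))
    s0 = float(np.clip(len(x) / 4.0, lo[3], hi[3]))
    for u0 in u_starts:
        p0 = np.clip([y0, a0, u0, s0], np.array(lo) + 1e-9, np.array(hi) - 1e-9)
        try:
            res = least_squares(
                lambda p: _gauss(x, *p) - y, p0, bounds=(lo, hi), method="trf",
                max_nfev=400,
            )
            sse = float(res.cost * 2.0)
            params = res.x
        except Exception:  # non-convergence: score at the start point
            sse = float(np.sum((_gauss(x, *p0) - y) ** 2))
            params = p0
        if best is None or sse < best[0]:
            best = (sse, params)
    return best


def classify_features(psth: Psth, epoch: str = "onset",
                      grid: TrialGrid | None = None) -> FeatureFit:
    """Classify the onset or offset shape of a normalised PSTH.

    The whole PSTH is min-max normalised before the epoch (onset
    0-300 ms, offset 1000-1500 ms) is extracted; each of the five
    descriptive Gaussians is fit by bounded least squares and the lowest
    residual wins, subject to two overrides: an epoch range < 0.2 is Flat
    by default, and Peak/Trough require a fitted extremum with prominence
    >= 0.2.
    """
    if epoch not in EPOCHS:
        raise ValueError(f"unknown epoch {epoch!r}")
    grid = grid or psth.grid
    t0, t1 = EPOCHS[epoch]
    y = psth.normalised()[grid.slice_ms(t0, t1)]
    E = len(y)
    x = np.arange(E, dtype=float)

    sse: dict = {}
    fits: dict = {}
    for name, boxes in _candidate_boxes(E).items():
        best = None
        for lo, hi in boxes:
            cand = _fit_candidate(x, y, lo, hi)
            if best is None or cand[0] < best[0]:
                best = cand
        sse[name] = best[0]
        fits[name] = dict(zip(("b", "a", "u", "sigma"), best[1]))

    if y.max() - y.min() < 0.2:
        return FeatureFit(epoch=epoch, label="Flat", params=fits["Flat"], sse=sse)

    eligible = dict(sse)
    for name, sign in (("Peak", 1.0), ("Trough", -1.0)):
        curve = sign * _gauss(x, **fits[name])
        peaks, props = find_peaks(curve, prominence=0.0)
        prom = props["prominences"].max() if len(peaks) else 0.0
        if prom < 0.2:
            eligible.pop(name, None)
    label = min(eligible, key=lambda k: (eligible[k], _PRECEDENCE[k]))
    return FeatureFit(epoch=epoch, label=label, params=fits[label], sse=sse)


# ---------------------------------------------------------------------------
# sustainedness
# ---------------------------------------------------------------------------


@dataclass
class SustainednessValue:
    index: float
    mean_delta_hz: float
    peak_delta_hz: float
    suppressed: bool


def sustainedness(psth: Psth, baseline_hz: float | None = None,
                  grid: TrialGrid | None = None) -> SustainednessValue:
    """Baseline-corrected mean / peak firing rate over the stimulus period.

    For responses whose mean exceeds baseline the peak is the maximal
    rate; for suppressed responses both mean and peak deltas are taken
    below baseline (peak = minimal rate), so the index stays in [0, 1]
    for excitatory and suppressed responses alike.  The index is 1 for a
    perfectly sustained response and tends to 0 for a transient one.
    """
    grid = grid or psth.grid
    if baseline_hz is None:
        baseline_hz = psth.baseline_mean_hz
    if not np.isfinite(baseline_hz):
        raise ValueError("baseline firing rate required (from blank trials)")
    seg = psth.rate_hz[grid.slice_ms(0.0, grid.stim_ms)]
    mean = seg.mean()
    if mean >= baseline_hz:
        mean_d = mean - baseline_hz
        peak_d = seg.max() - baseline_hz
        suppressed = False
    else:
        mean_d = baseline_hz - mean
        peak_d = baseline_hz - seg.min()
        suppressed = True
    if peak_d == 0:
        return SustainednessValue(np.nan, mean_d, peak_d, suppressed)
    return SustainednessValue(
        float(np.clip(mean_d / peak_d, 0.0, 1.0)), float(mean_d), float(peak_d),
        suppressed,
    )


# ---------------------------------------------------------------------------
# DTW sorting
# ---------------------------------------------------------------------------


def dtw_distance(x: np.ndarray, y: np.ndarray, band: int = 10) -> float:
    """Dynamic-time-warping distance with a Sakoe-Chiba band.

    Per-step cost is the absolute difference between (scalar) samples,
    summed along the optimal alignment path; warping is limited to
    ``band`` bins of stretch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if band < abs(n - m):
        raise ValueError("band smaller than length difference")
    INF = np.inf
    prev = np.full(m + 1, INF)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, INF)
        j_lo = max(1, i - band)
        j_hi = min(m, i + band)
        for j in range(j_lo, j_hi + 1):
            c = abs(x[i - 1] - y[j - 1])
            cur[j] = c + min(prev[j], cur[j - 1], prev[j - 1])
        prev = cur
    return float(prev[m])


def sort_psths(profiles: list[np.ndarray], band: int = 10) -> np.ndarray:
    """Order normalised PSTHs by DTW + average-linkage clustering.

    Returns the optimal leaf ordering (indices into ``profiles``) that
    minimises the sum of neighbouring-leaf distances.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to sort")
    P = np.asarray(profiles, dtype=float)
    if np.any(~np.isfinite(P)):
        raise ValueError("NaN/inf in PSTH profiles")
    n = len(P)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(P[i], P[j], band=band)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    Z = optimal_leaf_ordering(Z, condensed)
    return leaves_list(Z)


# ---------------------------------------------------------------------------
# unit filtering and cell types
# ---------------------------------------------------------------------------


def filter_and_type_units(units: pd.DataFrame) -> pd.DataFrame:
    """Quality-flag units and assign putative cell types.

    Quality requires ISI violations <= 10%, amplitude cut-off <= 10% and
    mean amplitude >= 50 uV.  Types: waveform duration <= 450 us ->
    narrow interneuron; otherwise pyramidal if the autocorrelogram rise
    time tau <= 6 ms, wide interneuron if tau > 6 ms (unassigned when
    tau is missing).
    """
    required = {"waveform_duration_us", "isi_violation_frac",
                "amp_cutoff_frac", "mean_amp_uv"}
    missing = required - set(units.columns)
    if missing:
        raise ValueError(f"missing unit metadata columns: {sorted(missing)}")
    out = units.copy()
    out["quality"] = (
        (out["isi_violation_frac"] <= 0.10)
        & (out["amp_cutoff_frac"] <= 0.10)
        & (out["mean_amp_uv"] >= 50.0)
    )
    dur = out["waveform_duration_us"]
    tau = out.get("acg_tau_ms", pd.Series(np.nan, index=out.index))
    cell_type = np.where(
        dur <= 450.0,
        "narrow interneuron",
        np.where(tau <= 6.0, "pyramidal",
                 np.where(tau > 6.0, "wide interneuron", "unassigned")),
    )
    cell_type = np.where((dur > 450.0) & tau.isna(), "unassigned", cell_type)
    out["cell_type"] = cell_type
    return out
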