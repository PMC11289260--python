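"""Synthetic session generator with known ground truth.

Generates spiking sessions that emulate the statistical structure of
extracellular recordings from mouse visual cortex during a visual-speed
discrimination protocol: 6 stimulus speeds x 2 behavioural states
(stationary / locomotion), 1 s stimulus + 1 s inter-stimulus interval,
~100-300 units, and latent population dynamics that differ by state:

* **stationary** trials: the latent state steps towards a speed-dependent
  steady state with a slow time constant and a damped ~4 Hz oscillation
  (spiral) superposed, giving transient, oscillatory population
  trajectories;
* **locomotion** trials: a fast first-order relaxation to a farther
  steady state, giving direct, sustained trajectories.

Spikes are drawn from inhomogeneous Poisson processes whose rates are
``softplus(loading @ latent + baseline + shared trial noise)``.  The
shared trial noise is a per-trial random vector whose covariance contains
a signed component along the signal (tuning) axis, so the alignment of
noise with signal correlations -- and hence the sign of the
signal-to-noise regression slope -- is controllable.

All randomness flows from a single seeded generator; regenerating with
the same config yields a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binning import BIN_MS, DEFAULT_GRID, TrialGrid
from .io import SessionBundle

STATES = ("stationary", "locomotion")


@dataclass(frozen=True)
class StateParams:
    """Latent-dynamics and noise parameters for one behavioural state.

    Parameters
    ----------
    onset_gain : float
        Scale of the speed-dependent steady-state displacement along the
        tuning direction (latent units).
    oscillation_freq_hz : float
        Frequency of the damped oscillation excited at stimulus onset and
        offset.  Must lie below the Nyquist frequency of the 10 ms grid.
    oscillation_amp : float
        Amplitude of the oscillation (latent units); ~0 gives the direct
        relaxation regime.
    damping : float
        Exponential decay rate of the oscillation envelope (1/s).
    relaxation_tau_ms : float
        Time constant of the first-order step towards the steady state.
    shared_noise_gain : float
        Standard-deviation scale of the shared (trial-varying) noise.
    noise_signal_alignment : float in [-1, 1]
        Signed weight of the signal-axis component of the shared-noise
        covariance.  +1 places correlated noise along the tuning axis
        (positive signal-noise regression slope), -1 anti-aligns it
        (negative slope), 0 leaves the shared noise isotropic.
    """

    onset_gain: float
    oscillation_freq_hz: float
    oscillation_amp: float
    damping: float
    relaxation_tau_ms: float
    shared_noise_gain: float
    noise_signal_alignment: float


def _default_state_params() -> dict:
    return {
        "stationary": StateParams(
            onset_gain=2.5,
            oscillation_freq_hz=4.0,
            oscillation_amp=2.0,
            damping=2.0,
            relaxation_tau_ms=150.0,
            shared_noise_gain=1.2,
            noise_signal_alignment=0.25,
        ),
        "locomotion": StateParams(
            onset_gain=4.0,
            oscillation_freq_hz=4.0,
            oscillation_amp=0.1,
            damping=2.0,
            relaxation_tau_ms=60.0,
            shared_noise_gain=1.0,
            noise_signal_alignment=0.25,
        ),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic session.

    Defaults mirror the targeted experimental protocol: 6 stimulus speeds
    x 2 states, 1 s stimulus + 1 s ISI, a 3-dimensional latent state
    (tuning axis + oscillation plane) and baseline rates drawn from a
    lognormal distribution typical of cortical populations.
    """

    n_units: int = 120
    n_trials_per_condition: int = 30
    n_blank_trials_per_state: int = 15
    stim_speeds: tuple = (10.0, 20.0, 40.0, 80.0, 160.0, 320.0)
    trial_window: TrialGrid = DEFAULT_GRID
    m_true: int = 3
    state_params: dict = field(default_factory=_default_state_params)
    baseline_rates: np.ndarray | None = None
    loading_scale: float = 1.0
    locomotion_speed_cm_s: float = 8.0
    block_len: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1 or self.n_trials_per_condition < 1:
            raise ValueError("counts must be positive")
        if self.m_true < 1:
            raise ValueError("m_true must be >= 1")
        nyquist = 1000.0 / BIN_MS / 2.0
        for name, sp in self.state_params.items():
            if not 0.0 < sp.oscillation_freq_hz < nyquist:
                raise ValueError(
                    f"{name}: oscillation_freq_hz must lie in (0, {nyquist})"
                )
            if not -1.0 <= sp.noise_signal_alignment <= 1.0:
                raise ValueError(f"{name}: noise_signal_alignment outside [-1, 1]")
        if self.baseline_rates is not None:
            if np.any(np.asarray(self.baseline_rates) < 0):
                raise ValueError("baseline rates must be >= 0")
            if len(self.baseline_rates) != self.n_units:
                raise ValueError("baseline_rates length != n_units")


@dataclass
class GroundTruth:
    """Generative quantities recorded alongside a synthetic bundle."""

    latents: dict  # (state, speed) -> (m_true, n_bins) trajectory
    loading: np.ndarray  # (n_units, m_true)
    baseline_rates: np.ndarray  # Hz
    tuning_curves: dict  # state -> (n_units, 6) steady-state rate (Hz)
    sustainedness: dict  # state -> designed index of the population rate
    trial_states: pd.Series  # trial_id -> state label

    def as_json_dict(self) -> dict:
        return {
            "latents": {f"{s}|{v}": traj for (s, v), traj in self.latents.items()},
            "loading": self.loading,
            "baseline_rates": self.baseline_rates,
            "tuning_curves": self.tuning_curves,
            "sustainedness": self.sustainedness,
            "trial_states": self.trial_states.to_dict(),
        }


def _speed_position(config: SynthConfig, speed: float) -> float:
    """Normalised position of a speed within the ordered speed set."""
    speeds = list(config.stim_speeds)
    if speed not in speeds:
        raise ValueError(f"unknown speed label {speed!r}; expected one of {speeds}")
    return (speeds.index(speed) + 1) / len(speeds)


def generate_latents(config: SynthConfig, state: str, speed: float) -> np.ndarray:
    """Noiseless latent trajectory for one condition.

    Returns an ``(m_true, n_bins)`` array on the 10 ms trial grid.  The
    first latent dimension carries the speed-dependent step; the second
    and third (when available) carry the damped oscillation excited at
    stimulus onset and offset.
    """
    config.validate()
    if state not in config.state_params:
        raise ValueError(f"unknown state label {state!r}; expected {STATES}")
    sp = config.state_params[state]
    grid = config.trial_window
    t = grid.centers_ms / 1000.0  # s, onset at 0
    stim_s = grid.stim_ms / 1000.0
    tau = sp.relaxation_tau_ms / 1000.0

    amp = sp.onset_gain * (0.4 + 0.6 * _speed_position(config, speed))
    z = np.zeros((config.m_true, grid.n_bins))

    # step along the tuning axis, first-order relaxation up then back down
    during = (t >= 0) & (t < stim_s)
    after = t >= stim_s
    if tau <= 1e-9:
        step = np.where(during, amp, 0.0)
    else:
        step = np.zeros_like(t)
        step[during] = amp * (1.0 - np.exp(-t[during] / tau))
        peak = amp * (1.0 - np.exp(-stim_s / tau))
        step[after] = peak * np.exp(-(t[after] - stim_s) / tau)
    z[0] = step

    # damped oscillation (spiral) excited at onset and at offset
    if sp.oscillation_amp != 0.0:
        w = 2.0 * np.pi * sp.oscillation_freq_hz
        for t0 in (0.0, stim_s):
            tt = t - t0
            active = tt >= 0
            env = sp.oscillation_amp * np.exp(-sp.damping * tt[active])
            sin_part = env * np.sin(w * tt[active])
            cos_part = env * (np.cos(w * tt[active]) - 1.0)
            if config.m_true >= 3:
                z[1, active] += sin_part
                z[2, active] += cos_part
            elif config.m_true == 2:
                z[1, active] += sin_part
            else:
                z[0, active] += sin_part
    return z


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-np.clip(y, 1e-10, None)))


def _sustainedness_of_profile(rate: np.ndarray, baseline: float,
                              stim: slice) -> float:
    seg = rate[stim]
    mean, peak = seg.mean(), seg.max()
    if mean < baseline:
        mean_d, peak_d = baseline - mean, baseline - seg.min()
    else:
        mean_d, peak_d = mean - baseline, peak - baseline
    return float(np.clip(mean_d / peak_d, 0.0, 1.0)) if peak_d > 0 else np.nan


def generate_session(config: SynthConfig) -> tuple[SessionBundle, GroundTruth]:
    """Generate a full synthetic session bundle plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = config.trial_window
    n_bins = grid.n_bins
    dt_s = BIN_MS / 1000.0

    # -- units -------------------------------------------------------------
    if config.baseline_rates is None:
        baseline = np.clip(rng.lognormal(1.3, 0.6, config.n_units), 0.5, 30.0)
    else:
        baseline = np.asarray(config.baseline_rates, dtype=float)
    L = rng.normal(0.0, config.loading_scale, (config.n_units, config.m_true))
    b_pre = _softplus_inv(baseline)
    u_sig = L[:, 0] / np.linalg.norm(L[:, 0])

    # -- condition latents and rate templates ------------------------------
    latents: dict = {}
    rate_templates: dict = {}
    for state in STATES:
        for speed in config.stim_speeds:
            z = generate_latents(config, state, speed)
            latents[(state, speed)] = z
            rate_templates[(state, speed)] = b_pre[:, None] + L @ z
        rate_templates[(state, None)] = np.tile(b_pre[:, None], (1, n_bins))

    # -- trial schedule ----------------------------------------------------
    # Trials of the same state run in consecutive blocks so locomotion
    # bouts are continuous and >= 5 s, as the changepoints criteria need.
    conditions: dict = {s: [] for s in STATES}
    for state in STATES:
        for speed in config.stim_speeds:
            conditions[state] += [(state, speed)] * config.n_trials_per_condition
        conditions[state] += [(state, None)] * config.n_blank_trials_per_state
        conditions[state] = [conditions[state][i]
                             for i in rng.permutation(len(conditions[state]))]

    period_s = (grid.stim_ms + grid.post_ms + grid.pre_ms) / 1000.0  # 2 s
    gap_s, lead_s = 4.0, 8.0
    schedule: list = []  # (onset_s, state, speed)
    t_cursor = lead_s
    queues = {s: list(c) for s, c in conditions.items()}
    order = []
    while any(queues.values()):
        for state in STATES:
            take = min(config.block_len, len(queues[state]))
            if take:
                order.append((state, [queues[state].pop(0) for _ in range(take)]))
    loco_blocks: list = []
    for state, block in order:
        block_first = t_cursor + grid.pre_ms / 1000.0
        for (st, speed) in block:
            onset = t_cursor + grid.pre_ms / 1000.0
            schedule.append((onset, st, speed))
            t_cursor += period_s
        if state == "locomotion":
            loco_blocks.append((block_first - grid.pre_ms / 1000.0,
                                t_cursor))
        t_cursor += gap_s
    total_s = t_cursor + lead_s

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(len(schedule)),
            "onset_s": [s[0] for s in schedule],
            "speed_deg_s": [s[2] if s[2] is not None else np.nan for s in schedule],
            "true_state": [s[1] for s in schedule],
        }
    )

    # -- behaviour traces --------------------------------------------------
    wheel_t = np.arange(0.0, total_s, dt_s)
    speed_tr = np.abs(rng.normal(0.0, 0.05, wheel_t.size))
    margin = 1.5
    for (b0, b1) in loco_blocks:
        sel = (wheel_t >= b0 - margin) & (wheel_t <= b1 + margin)
        speed_tr[sel] = config.locomotion_speed_cm_s + rng.normal(0.0, 0.8, sel.sum())
    # mild smoothing for continuity of the trace itself
    from .smoothing import gaussian_smooth

    speed_tr = np.clip(gaussian_smooth(speed_tr, sd_ms=50.0), 0.0, None)
    wheel = pd.DataFrame({"time_s": wheel_t, "speed_cm_s": speed_tr})

    ar = np.empty(wheel_t.size)
    ar[0] = 0.0
    eps = rng.normal(0.0, 0.03, wheel_t.size)
    for i in range(1, wheel_t.size):
        ar[i] = 0.98 * ar[i - 1] + eps[i]
    pupil_area = np.clip(1.0 + 0.04 * speed_tr + ar, 0.1, None)
    pupil = pd.DataFrame({"time_s": wheel_t, "area_au": pupil_area})

    # -- spikes ------------------------------------------------------------
    # Rates are piecewise-constant on the 10 ms grid, so Poisson counts
    # per bin with uniform placement inside the bin sample the
    # inhomogeneous process exactly at the analysis resolution.
    spike_unit: list = []
    spike_time: list = []
    bin_starts_s = grid.edges_ms[:-1] / 1000.0
    # Structured trial noise.  Positive alignment adds a common gain
    # factor along the tuning axis (unit-RMS loading, so per-unit
    # fluctuations are O(1)), which makes noise covariance proportional
    # to signal covariance.  Negative alignment removes the tuning-axis
    # component from isotropic trial noise, whose covariance
    # (I - u u^T) has off-diagonals exactly anti-proportional to the
    # signal covariance; positive-semidefiniteness caps their magnitude
    # at O(1/n_units), so anti-aligned noise correlations are weak by
    # mathematical necessity, not by choice.
    sqrtP = np.sqrt(config.n_units)
    h_aligned = u_sig * sqrtP
    _LAMBDA = 0.1  # private pre-activation jitter variance (relative)
    for onset, state, speed in schedule:
        sp = config.state_params[state]
        alpha = sp.noise_signal_alignment
        eps_vec = rng.normal(0.0, 1.0, config.n_units)
        w = rng.normal()
        if alpha >= 0:
            structured = np.sqrt(alpha) * w * h_aligned
        else:
            eta = rng.normal(0.0, 1.0, config.n_units)
            structured = np.sqrt(-alpha) * (eta - (eta @ u_sig) * u_sig)
        xi = sp.shared_noise_gain * (np.sqrt(_LAMBDA) * eps_vec + structured)
        act = rate_templates[(state, speed)] + xi[:, None]
        rate = _softplus(act)
        counts = rng.poisson(rate * dt_s)
        uu, bb = np.nonzero(counts)
        if uu.size:
            reps = counts[uu, bb]
            units_rep = np.repeat(uu, reps)
            bins_rep = np.repeat(bb, reps)
            times = onset + bin_starts_s[bins_rep] + rng.random(units_rep.size) * dt_s
            spike_unit.append(units_rep)
            spike_time.append(times)

    # baseline spiking outside trial windows keeps the session continuous
    windows = np.array([[o + grid.start_ms / 1000.0, o + grid.stop_ms / 1000.0]
                       for o, _, _ in schedule])
    gap_edges = np.concatenate([[0.0], windows.ravel(), [total_s]])
    gaps = gap_edges.reshape(-1, 2)
    gap_len = np.clip(gaps[:, 1] - gaps[:, 0], 0.0, None)
    total_gap = gap_len.sum()
    cum_gap = np.concatenate([[0.0], np.cumsum(gap_len)])
    for u in range(config.n_units):
        n_sp = rng.poisson(baseline[u] * total_gap)
        pos = np.sort(rng.random(n_sp)) * total_gap
        gi = np.searchsorted(cum_gap, pos, side="right") - 1
        times = gaps[gi, 0] + (pos - cum_gap[gi])
        spike_unit.append(np.full(n_sp, u))
        spike_time.append(times)

    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(spike_unit).astype(int),
            "time_s": np.concatenate(spike_time),
        }
    ).sort_values(["unit_id", "time_s"], kind="stable", ignore_index=True)

    # -- unit metadata -----------------------------------------------------
    narrow = rng.random(config.n_units) < 0.25
    duration = np.where(
        narrow,
        rng.normal(300.0, 40.0, config.n_units),
        rng.normal(620.0, 60.0, config.n_units),
    )
    acg_tau = rng.lognormal(1.1, 0.7, config.n_units)
    violations = rng.beta(1.0, 40.0, config.n_units)
    cutoff = rng.beta(1.0, 40.0, config.n_units)
    bad = rng.random(config.n_units) < 0.05
    violations = np.where(bad, 0.12 + 0.1 * rng.random(config.n_units), violations)
    amp = np.clip(rng.normal(130.0, 35.0, config.n_units), 20.0, None)
    mean_rate = np.array(
        [len(spikes[spikes["unit_id"] == u]) / total_s for u in range(config.n_units)]
    )
    units = pd.DataFrame(
        {
            "unit_id": np.arange(config.n_units),
            "mean_rate_hz": mean_rate,
            "waveform_duration_us": duration,
            "acg_tau_ms": acg_tau,
            "isi_violation_frac": violations,
            "amp_cutoff_frac": cutoff,
            "mean_amp_uv": amp,
        }
    )

    # -- ground truth ------------------------------------------------------
    stim = grid.slice_ms(0.0, grid.stim_ms)
    tuning = {}
    sust = {}
    for state in STATES:
        steady = grid.slice_ms(500.0, grid.stim_ms)
        curves = np.stack(
            [
                _softplus(rate_templates[(state, v)][:, steady]).mean(axis=1)
                for v in config.stim_speeds
            ],
            axis=1,
        )
        tuning[state] = curves
        pop_rate = np.stack(
            [_softplus(rate_templates[(state, v)]).mean(axis=0)
             for v in config.stim_speeds]
        ).mean(axis=0)
        sust[state] = _sustainedness_of_profile(
            pop_rate, float(_softplus(b_pre).mean()), stim
        )

    truth = GroundTruth(
        latents=latents,
        loading=L,
        baseline_rates=baseline,
        tuning_curves=tuning,
        sustainedness=sust,
        trial_states=trials.set_index("trial_id")["true_state"],
    )
    bundle = SessionBundle(
        units=units,
        spikes=spikes,
        trials=trials,
        wheel=wheel,
        pupil=pupil,
        ground_truth=truth.as_json_dict(),
    )
    return bundle, truth


def with_state_param(config: SynthConfig, state: str, **changes) -> SynthConfig:
    """Return a copy of ``config`` with one state's parameters updated."""
    params = dict(config.state_params)
    params[state] = replace(params[state], **changes)
    return replace(config, state_params=params)
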