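# Methods

This note documents the models and estimators implemented in `popdyn`,
the choices made where a design was genuinely open, and what the
synthetic-data validation does and does not establish about real
recordings.

## Time base and smoothing

All stages work on spike counts in 10 ms bins over a peri-stimulus
window from 200 ms before stimulus onset to 800 ms after stimulus offset
(2000 ms for a 1 s stimulus; 200 bins).  Firing-rate smoothing uses a
Gaussian kernel with 35 ms standard deviation, truncated at ±4 SD and
renormalised at trace edges, so smoothing a constant returns the same
constant and edge bins are not attenuated.  Sliding-window statistics
drop windows that would be truncated at either edge rather than padding
them.  Window midpoints are reported in milliseconds relative to
stimulus onset.

## Behavioural state

Wheel speed is derived from cumulative encoder ticks (radius →
distance → derivative at the native 60 Hz rate), resampled to 10 ms and
smoothed (35 ms SD).  Per-trial statistics are evaluated on the bins
whose centres fall in the 2000 ms trial window, with strict inequalities
at the bin level for thresholds like "> 75% of the window".

Three criteria sets label trials:

* **main** — stationary iff mean speed < 0.5 cm/s and speed < 3 cm/s
  for > 75% of the window; locomotion iff mean > 3 cm/s and speed >
  0.5 cm/s for > 75%; otherwise excluded.
* **stricter** — stationary iff speed < 0.5 cm/s throughout; locomotion
  iff mean > 3 cm/s and speed > 0.5 cm/s for ≥ 90%.
* **changepoints** — the session speed trace is z-scored, smoothed with
  a 400 ms-SD Gaussian and thresholded at 0.05 to open/close locomotion
  epochs; epochs with mean raw speed < 3 cm/s or duration < 5 s are
  dropped and survivors shrunk by 0.5 s at both ends.  A trial is
  locomotion iff its full window lies inside a surviving epoch.  The
  changepoints procedure intrinsically defines only the locomotion
  label; here a trial is stationary iff its window intersects no
  initial (unshrunk) epoch, and excluded otherwise.  A zero-variance (constant) trace cannot be
  z-scored; in that degenerate case the whole session is one epoch if
  its speed exceeds 3 cm/s and no epoch otherwise.

Note the 400 ms smoothing keeps the processed trace above the low 0.05
threshold roughly half a second beyond each raw bout edge, so raw bouts
slightly shorter than 5 s can still produce surviving epochs; this is a
property of the stated rule, not an implementation artefact.

Pupil-tertile (arousal) and speed-quartile partitions use per-trial
stimulus-period means; values equal to a boundary go to the lower group
so the partition is deterministic.  Condition balancing subsamples
uniformly at random (seeded) to the minimum count over the 12 speed ×
state conditions.

## PSTHs

PSTHs are trial means of 10 ms counts scaled to Hz and smoothed.
Reliability requires all three of: (1) firing-rate range ≥ 3 Hz;
(2) max |z| ≥ 3.29, where z-scores use the per-bin mean and SD of
smoothed single-trial rates over blank (no-stimulus) trials; (3) shape
reliability — 25 random half-splits of the trials, Pearson correlation
between the two half-PSTHs from stimulus onset onward, compared against
a null built by uniformly redistributing each trial's spikes over the
window (40 surrogates per split, 1000 total); the criterion passes if
the mean observed correlation exceeds the null at one-sided p ≤ 0.05
(z ≥ 1.645).  Because the observed statistic is a mean of 25 correlated
splits while the null SD is that of single surrogate draws, this test is
conservative under the null: its measured false-positive rate on
homogeneous Poisson units is ≈ 0.005, well below the nominal 5%.

Onset (0–300 ms) and offset (1000–1500 ms) response shapes are
classified by bounded least-squares fits of a Gaussian
`f(x) = b + a·exp(−(x−u)²/2σ²)` on the whole-PSTH min–max-normalised
trace.  Candidate-specific parameter boxes distinguish the shapes (for
an epoch of E bins): Decay and Rise each use two parameterisations
(positive-amplitude Gaussian centred off one end of the epoch, or its
negative mirror at the other end), with σ ∈ [2, 2E]; Peak and Trough
require an interior mean (u ∈ [0.1E, 0.9E]) and a narrow σ ∈ [2, E/3]
with amplitude sign distinguishing them; Flat pins |a| ≤ 0.05.  Five
restarts spread the initial u across its box.  The lowest residual wins,
subject to two overrides: an epoch range < 0.2 is Flat by default, and
Peak/Trough require a fitted extremum with prominence ≥ 0.2.  Ties break
towards the simpler shape (Flat, then Decay/Rise, then Peak/Trough).
The boxes are code-level constants and are the main deviation surface of
this classifier.

The sustainedness index is the baseline-corrected mean over the
stimulus period divided by the baseline-corrected peak; for suppressed
responses (mean below the blank-trial baseline) both deltas are taken
below baseline with the peak as the minimal rate, so the index lies in
[0, 1] for excitatory and suppressed responses alike and is clipped
there against floating-point excursions.

Response sorting computes pairwise dynamic-time-warping distances
(Sakoe–Chiba band of 10 bins, absolute per-step cost summed along the
optimal path), clusters with unweighted-average linkage and returns the
optimal leaf ordering.  Unit quality requires ISI violations ≤ 10%,
amplitude cut-off ≤ 10% and mean amplitude ≥ 50 µV; cell types follow
the waveform-duration/autocorrelogram-τ rule (≤ 450 µs narrow
interneuron; otherwise pyramidal iff τ ≤ 6 ms, wide interneuron iff
τ > 6 ms, unassigned when τ is missing).

## Tuning

Tuning strength per 200 ms window (10 ms step) is the cross-validated
R² described in the README, averaged over 3 stratified folds × 10
re-randomised repeats (folds are stratified by speed so no fold misses a
label; the 10 repeats fully re-randomise the splits).  The null permutes
speed labels across trials (100 shuffles, one CV evaluation each) and
takes the per-window 95th percentile.  Bouts require R² ≥ 0.1 and R² at
or above the null 95th percentile for ≥ 5 consecutive windows; start and
finish times are the midpoints of the first and last windows of the
first and last bouts, and the duration counts the 10 ms steps in all
bouts.

Calibration at desk scale (30 trials per speed): the per-window
exceedance probability of the null gate is ≈ 0.04 (slightly
conservative).  The per-unit false-bout rate, however, is ≈ 0.15–0.2
rather than 5%: with 10 ms steps the 181 windows overlap by 95%, so the
"5 consecutive windows" requirement spans only 240 ms and adds almost no
multiplicity correction over the per-window level.  At much larger trial
counts the absolute R² ≥ 0.1 gate becomes the binding constraint and the
per-unit rate falls; users should treat per-unit "tuned" flags at small
trial counts as exploratory.

## Correlations

Window counts (200 ms windows, 10 ms step) are correlated across trials
within a behavioural state (the six stimulus conditions pooled).  Signal
correlations are estimated by shuffling trials within condition
independently per unit and averaging the resulting Pearson correlations
over 10 shuffles (configurable); noise = total − signal elementwise, so
that identity is exact by construction.  Zero-variance units in a window
yield missing pairs that are excluded from summaries.

The 10-shuffle signal estimate carries pairing noise which, entering
signal and noise estimates with opposite signs, biases the per-window
noise-on-signal regression slope negative at small trial counts
(≈ −0.7 at 30 trials/condition even with zero true noise correlation).
Averaging ~100 shuffles makes this bias small relative to genuine
noise-correlation structure; analyses of slope sign in this package's
validation use 100 shuffles and the slope is averaged over
stimulus-period windows.

Temporal stability vectorises the upper off-diagonal triangle of each
window's matrix (row-major, fixed) and correlates window pairs
(pairwise-complete over missing entries); the lag-20 diagonal gives
neighbouring non-overlapping 200 ms windows.

## Factor analysis and trajectories

Counts are preprocessed by dropping units with mean smoothed rate
< 1 Hz, square-root transform, smoothing (35 ms SD) and per-unit
z-scoring (zero-variance units are dropped with a log entry).  The FA
model `x ~ N(μ, LLᵀ + Ψ)` is fit by EM on the sample covariance with a
PCA initialisation; the log-likelihood is tracked per iteration and is
non-decreasing (a small floor of 1e−8 on Ψ guards degeneracies), with
convergence at a relative improvement below 1e−8 (5000 iterations cap).
Dimensionality is chosen by 3-fold cross-validated held-out likelihood
over a grid of m.  Folds are formed over *trials*, not sample rows:
smoothed 10 ms samples within a trial are strongly dependent, and
row-level folding leaks training information into the held-out
likelihood, pushing the selected m to the top of the grid.  `m_opt` is
the smallest number of eigendimensions of LLᵀ explaining 95% of its
trace.  Single-trial latent trajectories are posterior means
`E[z|x] = Lᵀ(LLᵀ+Ψ)⁻¹(x−μ)` reshaped onto the trial grid; per-condition
trajectories are their trial means.  Sliding-window FA refits for
shared-variance dynamics use unsmoothed counts.

Trajectory metrics (onset epoch: transition start 0 ms, steady window
500–1000 ms; offset: 1000 ms and 1500–1800 ms):

* **Steady-state size and arrival.**  The steady-state size is the
  maximal distance of the trajectory from the steady-window centre
  within that window (the source formula prints a max over a sum
  evaluated at a single timepoint; the only usable reading is the
  instantaneous distance).  Arrival (T_end) is the midpoint of the
  first of ≥ 10 consecutive 200 ms sliding windows whose mean distance
  to the centre falls below that size, capped at the steady-window
  start.
* **Distance ratio** — cumulative path length between transition start
  and arrival over the direct distance; ≥ 1, with equality only for a
  straight monotone path.
* **Kinematics** — backward-difference path speed divided by the number
  of latent factors (the fitted model's m; configurable), acceleration
  as its derivative, and the acceleration periodogram on 0–20 Hz
  normalised by its band mean, with the 0–6 Hz share reported.
* **Angle of approach** — θ(t) between the reference vector (initial →
  final steady-window centres) and the vector from the trajectory to
  the final centre; undefined exactly at the centre, where the previous
  value is carried forward.  The cumulative angular deviation sums
  |Δθ| from the transition start to the *arrival time*: past arrival
  the angle is ill-conditioned (|b(t)| → 0) and the sum would
  accumulate estimation noise rather than path geometry.  The
  full-window variant remains available (`until_arrival=False`).
* **Tangling** — Q(t) as in the README with t′ restricted to ±100 ms
  and the first sample excluded (backward-difference velocity).  ε
  defaults to 0.1 × the mean squared distance of the trajectory from
  its grand mean; when comparing conditions or states, one shared ε
  should be pooled over all trajectories (`tangling_epsilon`), since a
  per-trajectory ε renormalises away genuine scale differences.  With
  the adaptive ε, tangling is invariant to translation and global
  rescaling of the trajectory.
* **Shared-variance metrics** — %SV_i = s_i/(s_i+ψ_i)·100 with
  s_i = (LLᵀ)_ii; loading similarity of the unit-normalised
  first-factor weight vector u is 1 − var(u)/(1/n) with the sample
  variance (divisor n−1), so equal weights score exactly 1 and a
  one-hot vector exactly 0; values are clipped to [0, 1] because
  sign-mixed vectors can otherwise score below 0.
* **Procrustes similarity** — the optimal translation, orthogonal
  rotation/reflection and isotropic scaling of the source onto the
  target (SVD solution); dissimilarity d = min SSE / scale of the
  centred target, and 1 − d is returned.  Applied to the onset window
  (0–300 ms) with factors truncated to m_opt.
* **Inter-trajectory distance** — per-timepoint mean Euclidean distance
  over the 15 unordered speed pairs.

## Decoding

The decoder is LDA with class means, a pooled covariance blended as
Σ_γ = (1−γ)Σ + γ·diag(Σ), and uniform priors over the six speeds
(conditions are balanced upstream).  γ = 1 is the independent-neuron
decoder.  A tiny ridge (1e−8 × mean diagonal) guards singular blends.
The δ threshold acts on standardised discriminant coefficients (the
per-feature maximal centred coefficient magnitude times the feature's
pooled SD); features below δ are dropped and the model refit once.
Hyperparameters are selected by a deterministic grid under inner 5-fold
CV (δ ∈ {0} ∪ a log-spaced grid, γ ∈ {0, 0.25, 0.5, 0.75, 1}) — a
reproducible replacement for wall-clock-dependent Bayesian optimisers
that tunes the same quantity.  Protocols: sliding 100 ms windows (10 ms
step) with stratified 3-fold CV × 5 repeats; the shuffle comparison on
100 ms/20 ms stimulus-period windows with Δ = (shuffled − chance) /
(intact − chance); cross-time training on non-overlapping 100 ms windows
(stratified 2-fold × 5 repeats) with relative performance referenced to
the matched train=test diagonal over the stimulus period;
latent-trajectory decoding on 50 ms windows of mean m-dimensional
position (full covariance, no search, 3-fold × 10 repeats); and
population-size curves with repetition count defaulting to half the
available units, capped.  All fold assignments derive from a single
seeded generator, so fixed seeds reproduce accuracies exactly.

## MUA spectrum

Per trial, the unit-mean 10 ms count series (trial mean removed) is
tapered with DPSS windows — time-bandwidth NW = 3 and 5 tapers by
default, standard multitaper practice for 2 s windows — and squared FFT
magnitudes are averaged over tapers, then trials, per condition.  The
2 s window gives a 0.5 Hz frequency grid; the 1–10 Hz band is reported
as power and as power normalised by the band mean (mean 1 by
construction).

## The synthetic session generator

The generator emulates the statistical structure of the recordings this
pipeline targets, not their biophysics.  Latent dynamics per condition:
stationary trials step towards a speed-dependent steady state with a
150 ms time constant and a damped oscillation (4 Hz, amplitude 2.0,
envelope decay 2 s⁻¹) excited at stimulus onset and offset in the
second/third latent dimensions — multi-cycle spirals; locomotion trials
relax directly (τ = 60 ms) to steady states spread further apart across
speeds (onset gain 4.0 vs 2.5).  The steady-state position scales
linearly along a fixed tuning direction with the speed's rank.  Rates
are `softplus(b + L·z + ξ)` with loadings of unit scale (pre-softplus
activations of order one, giving several-Hz tuning spreads typical of
visual cortex) and baseline rates lognormal (median ≈ 3.7 Hz, clipped
to [0.5, 30] Hz).  Softplus, rather than exp, keeps rates bounded under
large latent excursions.

ξ is a per-trial structured noise vector.  Positive noise–signal
alignment α adds a common gain factor along the tuning axis with
unit-RMS loading, making noise covariance proportional to signal
covariance (a positive noise-on-signal slope).  Negative α removes the
tuning-axis component from isotropic trial noise; the resulting
covariance ∝ I − ûûᵀ has off-diagonals exactly anti-proportional to the
signal covariance, but positive-semidefiniteness caps their magnitude
at O(1/n_units) — large uniformly anti-aligned noise correlations are
mathematically impossible, so the negative-slope regime is genuinely
weak.  Defaults (gain 1.2 stationary / 1.0 locomotion, α = 0.25) give
noise correlations of roughly 0.05 that partially limit decoding
(Δ decoding slightly above 1), consistent with cortical common-gain
fluctuations.

Spikes are sampled exactly: rates are piecewise-constant on the 10 ms
grid, so Poisson counts per bin with uniform placement within the bin
realise the inhomogeneous process at the analysis resolution.
Locomotion trials run in consecutive blocks so wheel bouts are
continuous and comfortably exceed the 5 s changepoints minimum; wheel
speed is ~8 cm/s during bouts and near zero otherwise, and pupil area
follows wheel speed plus slow AR(1) noise.  Unit metadata (waveform
duration, autocorrelogram τ, ISI violations, amplitude statistics) is
drawn so that ~95% of units pass quality control and all three cell
types occur.  All randomness flows from one seeded generator;
regenerating with the same config reproduces the bundle exactly.

**What passing the synthetic validation shows** — that every estimator
recovers the structure it targets when that structure is present and
stays calibrated when it is absent, at desk scale (100 units, 30
trials/condition).  **What it does not show** — the generator's tuning
is one-dimensional (a single population axis rather than diverse
preferred speeds), oscillations are deterministic per condition (no
phase jitter across trials), trial noise is constant within a trial,
and there are no slow drifts, adaptation or eye movements; absolute
values of decoding accuracy, %SV or tangling on real recordings will
differ even where the state contrasts reproduce.

## Problem sizes used in validation

Formula identities and oracle equivalences run on small constructed
inputs in seconds.  Null calibrations use 500 simulated units each for
the tuning and reliability statistics (with 2 CV repeats / 40 shuffles
for tuning, against the full 10 / 100 used in analysis).  Recovery and
state-contrast checks run on sessions of 100 units × 30
trials/condition (dimensionality, contrasts) and 50–60 units
(noise-correlation and slope-sign probes), sizes at which every check
completes on a single CPU in a few minutes while leaving the tested
effects well above their estimation noise.
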