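"""Multitaper spectrum of multi-unit activity by behavioural state.

Computes the 1-10 Hz normalised power spectrum of population-mean spike
counts per condition and prints where each state's spectrum peaks.
"""

import numpy as np

import popdyn as P

bundle, truth = P.generate_session(
    P.SynthConfig(n_units=80, n_trials_per_condition=30,
                  n_blank_trials_per_state=5, seed=42)
)
counts = bundle.binned_counts()
tr = bundle.trials
stim = tr["speed_deg_s"].notna().to_numpy()
states = tr["true_state"].to_numpy()
speeds = tr["speed_deg_s"].to_numpy()

for state in ("stationary", "locomotion"):
    spectra = []
    for v in np.unique(speeds[stim]):
        sel = (states == state) & (speeds == v)
        res = P.mua_spectrum(counts[sel])
        spectra.append(res.norm_power)
    mean_spec = np.mean(spectra, axis=0)
    peak = res.freq_hz[np.argmax(mean_spec)]
    print(f"{state:>11}: normalised power peaks at {peak:.1f} Hz "
          f"(max {mean_spec.max():.2f}, mean over band = 1 by construction)")
# The normalised spectrum equals 1 on average over 1-10 Hz; departures
# from flatness mark rhythmic structure in the population rate.
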