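"""Sliding-window tuning strength with shuffle-null bout detection.

Computes the cross-validated tuning R^2 over 200 ms windows for one
well-tuned unit in each behavioural state, detects tuning bouts against
the label-shuffle null, and prints when tuning starts and how long it
lasts.
"""

import numpy as np

import popdyn as P

bundle, truth = P.generate_session(
    P.SynthConfig(n_units=60, n_trials_per_condition=30,
                  n_blank_trials_per_state=5, seed=42)
)
counts = bundle.binned_counts()
tr = bundle.trials
stim = tr["speed_deg_s"].notna().to_numpy()
states = tr["true_state"].to_numpy()
speeds = tr["speed_deg_s"].to_numpy()

u = int(np.argmax(np.ptp(truth.tuning_curves["locomotion"], axis=1)))
print(f"unit {u}: steady-state rates across speeds "
      f"{np.round(truth.tuning_curves['locomotion'][u], 1)} Hz (locomotion)")

for state in ("stationary", "locomotion"):
    sel = (states == state) & stim
    prof = P.tuning_profile(counts[sel][:, u, :], speeds[sel], rng=1)
    peak = np.nanmax(prof.r2)
    if prof.tuned:
        print(f"{state:>11}: peak R^2 {peak:.2f}, tuned from "
              f"{prof.start_ms:.0f} ms to {prof.finish_ms:.0f} ms "
              f"({prof.duration_ms:.0f} ms in bouts)")
    else:
        print(f"{state:>11}: peak R^2 {peak:.2f}, no tuning bout")
# With its faster dynamics and wider tuning spread, the locomotion state
# typically reaches significant tuning earlier in the trial.
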