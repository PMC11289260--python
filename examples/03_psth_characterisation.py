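"""PSTHs, reliability, descriptive onset features and sustainedness.

For the most strongly driven unit of a synthetic session, builds the
per-state PSTHs, runs the three-criterion reliability test, classifies
the onset shape with the constrained Gaussian fits, and compares the
sustainedness index between behavioural states.
"""

import numpy as np

import popdyn as P

bundle, truth = P.generate_session(
    P.SynthConfig(n_units=60, n_trials_per_condition=30,
                  n_blank_trials_per_state=15, seed=42)
)
counts = bundle.binned_counts()
tr = bundle.trials
stim = tr["speed_deg_s"].notna().to_numpy()
states = tr["true_state"].to_numpy()

u = int(np.argmax(truth.loading[:, 0]))
print(f"unit {u}: baseline {truth.baseline_rates[u]:.1f} Hz, "
      f"tuning-axis loading {truth.loading[u, 0]:.2f}")

for state in ("stationary", "locomotion"):
    sel = (states == state) & stim
    blanks = counts[(states == state) & ~stim][:, u, :]
    psth = P.build_psth(counts[sel][:, u, :])
    baseline, _ = P.baseline_stats(blanks)
    rel = P.assess_reliability(counts[sel][:, u, :], blanks, rng=0)
    fit = P.classify_features(psth, "onset")
    sus = P.sustainedness(psth, baseline)
    print(f"{state:>11}: range {psth.range_hz:5.1f} Hz | reliable="
          f"{rel.reliable} (z_shape={rel.shape_z:5.1f}) | onset feature "
          f"{fit.label:<6} | sustainedness {sus.index:.2f}")
# Locomotion responses plateau (sustainedness near the top of the range)
# while stationary responses carry an oscillatory transient and score lower.
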