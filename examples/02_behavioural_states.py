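"""Classify trials into behavioural states and balance condition counts.

Applies the three criteria sets (main, stricter, changepoints) to the
wheel trace of a synthetic session, partitions stationary trials by
pupil-area tertiles, and downsamples so all 12 speed-by-state conditions
hold equally many trials.
"""

import popdyn as P

bundle, truth = P.generate_session(
    P.SynthConfig(n_units=30, n_trials_per_condition=12,
                  n_blank_trials_per_state=6, seed=42)
)

for criteria in ("main", "stricter", "changepoints"):
    table = P.classify_trials(bundle.wheel, bundle.trials, criteria)
    counts = table["state"].value_counts().to_dict()
    agree = (
        table.merge(bundle.trials, on="trial_id")
        .query("state != 'excluded'")
        .pipe(lambda d: (d["state"] == d["true_state"]).mean())
    )
    print(f"{criteria:>12}: {counts}  agreement with ground truth "
          f"{agree:.3f}")

main = P.classify_trials(bundle.wheel, bundle.trials, "main")
stationary = bundle.trials.merge(main.query("state == 'stationary'"),
                                 on="trial_id")
arousal = P.partition_trials(bundle.pupil, stationary, "pupil_tertiles")
print("arousal partition of stationary trials:",
      arousal["label"].value_counts().to_dict())

balanced = P.balance_conditions(main, bundle.trials, seed=0)
sizes = balanced.groupby(["state", "speed_deg_s"]).size()
print(f"balanced: {sizes.min()} trials in each of {len(sizes)} conditions")
# Every condition ends with the same trial count, so state comparisons
# downstream are not confounded by unequal sampling.
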