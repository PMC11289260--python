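import numpy as np
import pytest

import popdyn as P


@pytest.fixture(scope="session")
def small_session():
    """A compact synthetic session shared by fast integration tests."""
    cfg = P.SynthConfig(
        n_units=40, n_trials_per_condition=12, n_blank_trials_per_state=10, seed=7
    )
    bundle, truth = P.generate_session(cfg)
    counts = bundle.binned_counts()
    return {"cfg": cfg, "bundle": bundle, "truth": truth, "counts": counts}


@pytest.fixture(scope="session")
def acceptance_session():
    """Synthetic session at the scaled-down recovery size (100 units,
    30 trials per condition)."""
    cfg = P.SynthConfig(
        n_units=100, n_trials_per_condition=30, n_blank_trials_per_state=15, seed=11
    )
    bundle, truth = P.generate_session(cfg)
    counts = bundle.binned_counts()
    tr = bundle.trials
    return {
        "cfg": cfg,
        "bundle": bundle,
        "truth": truth,
        "counts": counts,
        "states": tr["true_state"].to_numpy(),
        "speeds": tr["speed_deg_s"].to_numpy(),
        "stim": tr["speed_deg_s"].notna().to_numpy(),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
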