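"""Thin wrappers over standard statistical models.

Group-level inference in this field (behavioural-state effects on
sustainedness, tuning times, correlations, decoding) uses mixed-effects
models and McNemar tests from standard libraries; the pipeline exports
tidy tables and these convenience wrappers only assemble the call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def fit_state_lme(
    table: pd.DataFrame,
    value_col: str,
    state_col: str = "state",
    group_col: str = "subject",
):
    """Random-intercept linear mixed model ``value ~ state + (1 | group)``.

    Returns the fitted statsmodels ``MixedLMResults``.
    """
    import statsmodels.formula.api as smf

    df = table[[value_col, state_col, group_col]].dropna().copy()
    model = smf.mixedlm(f"{value_col} ~ C({state_col})", df, groups=df[group_col])
    return model.fit(reml=True)


def mcnemar_state_proportions(flags_a, flags_b):
    """McNemar test on paired boolean outcomes (e.g. reliable per state)."""
    from statsmodels.stats.contingency_tables import mcnemar

    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    table = np.array(
        [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
    )
    return mcnemar(table, exact=True)
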