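"""Tidy-table exporters for pipeline results.

Each helper flattens a result object into a long-format DataFrame ready
to be written as TSV or fed to a mixed-effects model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def psth_table(psths) -> pd.DataFrame:
    """Long table (unit, state, speed, time_ms, rate_hz) from Psth objects."""
    rows = []
    for p in psths:
        t = p.grid.centers_ms
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": p.unit_id,
                    "state": p.state,
                    "speed_deg_s": p.speed,
                    "time_ms": t,
                    "rate_hz": p.rate_hz,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def tuning_table(profiles: dict) -> pd.DataFrame:
    """Per-window tuning table from {(unit, state): TuningProfile}."""
    rows = []
    for (unit, state), prof in profiles.items():
        in_bout = np.zeros(len(prof.window_mid_ms), dtype=bool)
        for a, b in prof.bouts:
            in_bout |= (prof.window_mid_ms >= a) & (prof.window_mid_ms <= b)
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": unit,
                    "state": state,
                    "window_mid_ms": prof.window_mid_ms,
                    "r2": prof.r2,
                    "null95": prof.null95,
                    "in_bout": in_bout,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def tuning_summary_table(profiles: dict) -> pd.DataFrame:
    rows = [
        {
            "unit_id": unit,
            "state": state,
            "tuned": prof.tuned,
            "start_ms": prof.start_ms,
            "finish_ms": prof.finish_ms,
            "duration_ms": prof.duration_ms,
        }
        for (unit, state), prof in profiles.items()
    ]
    return pd.DataFrame(rows)


def correlation_summary_table(tensors: dict) -> pd.DataFrame:
    """Per-window summary from {state: CorrelationTensor}."""
    from .correlations import signal_noise_slope

    rows = []
    for state, ct in tensors.items():
        rows.append(
            pd.DataFrame(
                {
                    "state": state,
                    "window_mid_ms": ct.window_mid_ms,
                    "mean_abs_signal": ct.mean_abs("signal"),
                    "mean_abs_noise": ct.mean_abs("noise"),
                    "slope": signal_noise_slope(ct),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def decoding_table(results: dict) -> pd.DataFrame:
    """Per-window accuracies from {state: DecodingResult}."""
    rows = []
    for state, res in results.items():
        rows.append(
            pd.DataFrame(
                {
                    "state": state,
                    "window_mid_ms": res.window_mid_ms,
                    "accuracy": res.accuracy,
                    "chance": res.chance,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
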