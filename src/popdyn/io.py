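"""Session bundle container and on-disk format.

A *session bundle* is the single input object for all analysis stages:
per-unit spike times, a trial table, a wheel (locomotion) trace, an
optional pupil-area trace and per-unit metadata.  On disk a bundle is a
directory of plain TSV tables plus an optional ``ground_truth.json``
written by the synthetic generator.

Blank (no-stimulus) trials are rows of the trial table whose
``speed_deg_s`` is NaN; they provide the baseline statistics used by the
PSTH reliability and sustainedness analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import DEFAULT_GRID, TrialGrid, bin_spikes

UNIT_COLUMNS = [
    "unit_id",
    "mean_rate_hz",
    "waveform_duration_us",
    "acg_tau_ms",
    "isi_violation_frac",
    "amp_cutoff_frac",
    "mean_amp_uv",
]


@dataclass
class SessionBundle:
    """In-memory recording session.

    Attributes
    ----------
    units : DataFrame
        One row per unit with quality metrics (see ``UNIT_COLUMNS``).
    spikes : DataFrame
        Columns ``unit_id`` and ``time_s``; rows need not be sorted.
    trials : DataFrame
        Columns ``trial_id``, ``onset_s``, ``speed_deg_s`` (NaN on blank
        trials) and, for synthetic sessions, ``true_state``.
    wheel : DataFrame
        Columns ``time_s``, ``speed_cm_s`` on a uniform 10 ms grid.
    pupil : DataFrame or None
        Columns ``time_s``, ``area_au``.
    ground_truth : dict or None
        Generative ground truth for synthetic sessions.
    """

    units: pd.DataFrame
    spikes: pd.DataFrame
    trials: pd.DataFrame
    wheel: pd.DataFrame
    pupil: pd.DataFrame | None = None
    ground_truth: dict | None = None
    _spike_index: dict = field(default_factory=dict, repr=False)

    # -- accessors ---------------------------------------------------------

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    @property
    def stim_speeds(self) -> np.ndarray:
        """Sorted unique stimulus speeds (blanks excluded)."""
        s = self.trials["speed_deg_s"].dropna().unique()
        return np.sort(s)

    def blank_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["speed_deg_s"].isna()]

    def stimulus_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["speed_deg_s"].notna()]

    def spike_times(self, unit_id) -> np.ndarray:
        """Sorted spike times (s) of one unit, cached."""
        if unit_id not in self._spike_index:
            t = self.spikes.loc[self.spikes["unit_id"] == unit_id, "time_s"]
            self._spike_index[unit_id] = np.sort(t.to_numpy(dtype=float))
        return self._spike_index[unit_id]

    def binned_counts(
        self,
        trial_ids=None,
        unit_ids=None,
        grid: TrialGrid = DEFAULT_GRID,
    ) -> np.ndarray:
        """Spike-count tensor of shape (n_trials, n_units, n_bins)."""
        trials = self.trials
        if trial_ids is not None:
            trials = trials.set_index("trial_id").loc[list(trial_ids)].reset_index()
        onsets = trials["onset_s"].to_numpy(dtype=float)
        if unit_ids is None:
            unit_ids = self.unit_ids
        out = np.empty((len(onsets), len(unit_ids), grid.n_bins), dtype=np.int64)
        for j, uid in enumerate(unit_ids):
            out[:, j, :] = bin_spikes(self.spike_times(uid), onsets, grid)
        return out

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> Path:
        """Write the bundle as a directory of TSV tables (+ JSON truth)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.units.to_csv(d / "units.tsv", sep="\t", index=False)
        self.spikes.to_csv(d / "spikes.tsv", sep="\t", index=False, float_format="%.4f")
        self.trials.to_csv(d / "trials.tsv", sep="\t", index=False)
        self.wheel.to_csv(d / "wheel.tsv", sep="\t", index=False, float_format="%.4f")
        if self.pupil is not None:
            self.pupil.to_csv(d / "pupil.tsv", sep="\t", index=False, float_format="%.4f")
        if self.ground_truth is not None:
            with open(d / "ground_truth.json", "w") as fh:
                json.dump(self.ground_truth, fh, default=_jsonable)
        return d

    @classmethod
    def load(cls, directory) -> "SessionBundle":
        d = Path(directory)
        pupil = None
        if (d / "pupil.tsv").exists():
            pupil = pd.read_csv(d / "pupil.tsv", sep="\t")
        truth = None
        if (d / "ground_truth.json").exists():
            with open(d / "ground_truth.json") as fh:
                truth = json.load(fh)
        return cls(
            units=pd.read_csv(d / "units.tsv", sep="\t"),
            spikes=pd.read_csv(d / "spikes.tsv", sep="\t"),
            trials=pd.read_csv(d / "trials.tsv", sep="\t"),
            wheel=pd.read_csv(d / "wheel.tsv", sep="\t"),
            pupil=pupil,
            ground_truth=truth,
        )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return np.round(obj, 6).tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
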