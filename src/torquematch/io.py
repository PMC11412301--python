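"""Plain-text trial storage: one CSV per trial plus JSON sidecars.

Layout under a cohort directory::

    cohort.json                      # per-participant reference values
    P01/trial_000.csv                # time_s, torques, emg_* columns
    P01/trial_000.json               # load, events, is_practice, ...

Everything is round-trippable so the analysis can run from disk as well
as from in-memory cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from torquematch.config import MUSCLES
from torquematch.synthetic import ParticipantReference, TrialRecording

_EMG_COLS = [f"emg_{m.lower()}" for m in MUSCLES]


def write_trial(trial: TrialRecording, directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"trial_{trial.trial_index:03d}_load{trial.load_condition:g}"
    n = len(trial.elbow_torque)
    data = {"time_s": np.arange(n) / trial.sample_rate,
            "elbow_torque_nm": trial.elbow_torque,
            "shoulder_torque_nm": trial.shoulder_torque}
    if trial.emg is not None:
        for m, col in enumerate(_EMG_COLS):
            data[col] = trial.emg[m]
    pd.DataFrame(data).to_csv(directory / f"{stem}.csv", index=False,
                              float_format="%.6g")
    sidecar = {"participant_id": trial.participant_id,
               "load_condition": trial.load_condition,
               "trial_index": trial.trial_index,
               "is_practice": trial.is_practice,
               "sample_rate": trial.sample_rate,
               "events": trial.events}
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return directory / f"{stem}.csv"


def read_trial(csv_path: Path) -> TrialRecording:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    emg = None
    if all(c in df.columns for c in _EMG_COLS):
        emg = df[_EMG_COLS].to_numpy().T
    return TrialRecording(
        participant_id=meta["participant_id"],
        load_condition=meta["load_condition"],
        trial_index=meta["trial_index"],
        is_practice=meta["is_practice"],
        sample_rate=meta["sample_rate"],
        elbow_torque=df["elbow_torque_nm"].to_numpy(),
        shoulder_torque=df["shoulder_torque_nm"].to_numpy(),
        emg=emg, events=meta["events"],
    )


def write_cohort(cohort, directory: Path) -> Path:
    """Write a generated cohort (list of (reference, trials)) to disk."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    refs = {}
    for ref, trials in cohort:
        refs[ref.participant_id] = {
            "mvt_ef": ref.mvt_ef, "mvt_sabd": ref.mvt_sabd,
            "mvc_emg_peak": ref.mvc_emg_peak.tolist(),
        }
        for trial in trials:
            write_trial(trial, directory / ref.participant_id)
    (directory / "cohort.json").write_text(json.dumps(refs, indent=1))
    return directory


def read_cohort(directory: Path):
    directory = Path(directory)
    refs = json.loads((directory / "cohort.json").read_text())
    cohort = []
    for pid in sorted(refs):
        ref = ParticipantReference(
            participant_id=pid, mvt_ef=refs[pid]["mvt_ef"],
            mvt_sabd=refs[pid]["mvt_sabd"],
            mvc_emg_peak=np.array(refs[pid]["mvc_emg_peak"]))
        trials = [read_trial(p) for p in
                  sorted((directory / pid).glob("trial_*.csv"))]
        cohort.append((ref, trials))
    return cohort
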