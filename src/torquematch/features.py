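"""Per-trial torque-generation features and trial-validity rules.

Analysis windows (half-open, sample index floored):

* reference segment — 0.5 s starting at the reference-phase "hold" cue;
  used for the reference torque, the force-steadiness CV, coactivation,
  and the phase-averaged EMG envelopes;
* match segment — 0.25 s before to 0.25 s after the match-phase "hold"
  cue; used for the matched torque.

A trial is excluded when it is a practice trial, when the match-phase
shoulder torque reaches 10 % MVT_SABD (the protocol's abort threshold),
or when a required cue or window is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from torquematch.config import MUSCLES
from torquematch.emg import process_channel
from torquematch.synthetic import ParticipantReference, TrialRecording

REFERENCE_WINDOW_S = 0.5
MATCH_HALF_WINDOW_S = 0.25
SHOULDER_MATCH_LIMIT = 0.10  # fraction of MVT_SABD

PHASES = ("reference", "match")


class SegmentError(ValueError):
    """A required cue or analysis window is unavailable."""


@dataclass
class TrialFeatures:
    """Derived quantities for one trial (NaN where undefined)."""

    participant_id: str
    load_condition: float
    trial_index: int
    tau_reference: float = np.nan  # Nm
    tau_match: float = np.nan      # Nm
    tau_err: float = np.nan        # Nm, tau_match - tau_reference
    cv: float = np.nan             # percent
    coactivation: float = np.nan   # percent
    t_ref: float = np.nan          # s
    mean_norm_emg: np.ndarray | None = None  # (8, 2) percent MVC
    shoulder_ref_mean: float = np.nan   # Nm
    shoulder_match_max: float = np.nan  # Nm
    valid: bool = True
    reasons: list[str] = field(default_factory=list)


def _segment_slice(t_start: float, duration: float, sample_rate: float,
                   n: int) -> slice:
    i0 = int(np.floor(t_start * sample_rate))
    i1 = i0 + int(round(duration * sample_rate))
    if i0 < 0 or i1 > n:
        raise SegmentError("analysis window exceeds recording bounds")
    return slice(i0, i1)


def extract_reference_segment(trial: TrialRecording) -> slice:
    """Sample slice for the 0.5 s reference window after the "hold" cue."""
    if "hold_ref" not in trial.events:
        raise SegmentError("hold_ref cue missing")
    return _segment_slice(trial.events["hold_ref"], REFERENCE_WINDOW_S,
                          trial.sample_rate, len(trial.elbow_torque))


def extract_match_segment(trial: TrialRecording) -> slice:
    """Sample slice for the 0.5 s window centered on the match "hold" cue."""
    if "hold_match" not in trial.events:
        raise SegmentError("hold_match cue missing")
    return _segment_slice(trial.events["hold_match"] - MATCH_HALF_WINDOW_S,
                          2 * MATCH_HALF_WINDOW_S, trial.sample_rate,
                          len(trial.elbow_torque))


def compute_cv(segment: np.ndarray) -> float:
    """Coefficient of variation of the held torque: sd/mean x 100 (sample
    SD, n-1 denominator)."""
    segment = np.asarray(segment, dtype=float)
    mean = segment.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean torque")
    return float(segment.std(ddof=1) / mean * 100.0)


def compute_coactivation(mean_bic: float, mean_tri: float) -> float:
    """Triceps share of summed biceps+triceps activity, percent."""
    total = mean_bic + mean_tri
    if total <= 0:
        raise ValueError("coactivation undefined when both activities are 0")
    return float(mean_tri / total * 100.0)


def compute_tref(trial: TrialRecording) -> float:
    """Time to stabilize: "in" cue to reference-phase "hold" cue (s)."""
    if "in" not in trial.events or "hold_ref" not in trial.events:
        raise SegmentError("in/hold_ref cues required for T_ref")
    tref = trial.events["hold_ref"] - trial.events["in"]
    if tref <= 0:
        raise SegmentError("T_ref must be strictly positive")
    return float(tref)


def validate_trial(trial: TrialRecording,
                   ref: ParticipantReference) -> tuple[bool, list[str]]:
    """Apply the exclusion rules; returns (valid, reasons)."""
    reasons: list[str] = []
    if trial.is_practice:
        reasons.append("practice")
    missing = [k for k in TrialRecording.EVENT_ORDER
               if k not in trial.events]
    if missing:
        reasons.append(f"missing events: {', '.join(missing)}")
    else:
        try:
            extract_reference_segment(trial)
            extract_match_segment(trial)
            compute_tref(trial)
        except SegmentError as exc:
            reasons.append(str(exc))
        sl = _match_phase_slice(trial)
        if trial.shoulder_torque[sl].max() >= SHOULDER_MATCH_LIMIT * ref.mvt_sabd:
            reasons.append("match-phase shoulder torque >= 10% MVT_SABD")
    return len(reasons) == 0, reasons


def _match_phase_slice(trial: TrialRecording) -> slice:
    i0 = int(np.floor(trial.events["match"] * trial.sample_rate))
    i1 = int(np.floor(trial.events["relax_end"] * trial.sample_rate))
    return slice(i0, i1)


def compute_trial_features(trial: TrialRecording,
                           ref: ParticipantReference) -> TrialFeatures:
    """Extract all per-trial features; invalid trials carry reason codes.

    EMG-derived quantities (phase-averaged envelopes, coactivation) are
    NaN when the trial carries no EMG.
    """
    feats = TrialFeatures(participant_id=trial.participant_id,
                          load_condition=trial.load_condition,
                          trial_index=trial.trial_index)
    feats.valid, feats.reasons = validate_trial(trial, ref)
    try:
        ref_sl = extract_reference_segment(trial)
        match_sl = extract_match_segment(trial)
    except SegmentError:
        return feats

    ref_seg = trial.elbow_torque[ref_sl]
    match_seg = trial.elbow_torque[match_sl]
    feats.tau_reference = float(ref_seg.mean())
    feats.tau_match = float(match_seg.mean())
    feats.tau_err = feats.tau_match - feats.tau_reference
    try:
        feats.cv = compute_cv(ref_seg)
    except ValueError:
        feats.reasons.append("cv undefined")
        feats.valid = False
    try:
        feats.t_ref = compute_tref(trial)
    except SegmentError:
        pass
    feats.shoulder_ref_mean = float(trial.shoulder_torque[ref_sl].mean())
    feats.shoulder_match_max = float(
        trial.shoulder_torque[_match_phase_slice(trial)].max())

    if trial.emg is not None:
        env = np.empty((len(MUSCLES), 2))
        for m, muscle in enumerate(MUSCLES):
            series = process_channel(trial.emg[m], ref.mvc_emg_peak[m],
                                     trial.sample_rate, muscle=muscle)
            env[m, 0] = series.values[ref_sl].mean()
            env[m, 1] = series.values[match_sl].mean()
        feats.mean_norm_emg = env
        bic = env[MUSCLES.index("BIC"), 0]
        tri = env[MUSCLES.index("TRI"), 0]
        try:
            feats.coactivation = compute_coactivation(bic, tri)
        except ValueError:
            feats.reasons.append("coactivation undefined")
    return feats


def features_table(features: list[TrialFeatures]) -> pd.DataFrame:
    """Tidy per-trial table (one row per trial) for export and stats."""
    rows = []
    for f in features:
        row = {
            "participant": f.participant_id,
            "load": f.load_condition,
            "trial": f.trial_index,
            "tau_reference": f.tau_reference,
            "tau_match": f.tau_match,
            "tau_err": f.tau_err,
            "cv": f.cv,
            "coactivation": f.coactivation,
            "t_ref": f.t_ref,
            "shoulder_ref_mean": f.shoulder_ref_mean,
            "shoulder_match_max": f.shoulder_match_max,
            "valid": f.valid,
            "reasons": ";".join(f.reasons),
        }
        if f.mean_norm_emg is not None:
            for m, muscle in enumerate(MUSCLES):
                row[f"emg_{muscle.lower()}_ref"] = f.mean_norm_emg[m, 0]
                row[f"emg_{muscle.lower()}_match"] = f.mean_norm_emg[m, 1]
        rows.append(row)
    return pd.DataFrame(rows)
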