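"""Perceptual outcomes of torque matching: constant and variable error.

The constant error (CE) is the mean signed matching error
tau_err = tau_match - tau_reference over a participant's valid testing
trials at one shoulder load — positive CE means the reproduced torque
overshoots the reference.  The variable error (VE) is the sample standard
deviation of tau_err, measuring matching precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_ce(errors) -> float:
    """Constant error: arithmetic mean of the matching errors (Nm)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("CE requires at least one matching error")
    return float(errors.mean())


def compute_ve(errors) -> float:
    """Variable error: sample SD of the matching errors (Nm)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("VE requires at least two matching errors")
    return float(errors.std(ddof=1))


def summarize_perception(features: pd.DataFrame) -> pd.DataFrame:
    """Per participant x load CE/VE over valid trials.

    Expects the tidy per-trial features table; rows with fewer than two
    valid trials report VE as NaN, cells with none are dropped.
    """
    valid = features[features["valid"]]
    rows = []
    for (pid, load), grp in valid.groupby(["participant", "load"],
                                          sort=True):
        errs = grp["tau_err"].to_numpy()
        if errs.size == 0:
            continue
        rows.append({
            "participant": pid,
            "load": load,
            "ce_nm": compute_ce(errs),
            "ve_nm": compute_ve(errs) if errs.size >= 2 else np.nan,
            "n_trials": int(errs.size),
        })
    return pd.DataFrame(rows)
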