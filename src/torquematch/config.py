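"""Generator configuration and protocol constants.

The defaults emulate the torque-matching protocol this package analyzes:
blocks of 10 trials (first 2 practice) at shoulder abduction loads of
10/30/50 % MVT_SABD with an elbow flexion target of 25 % MVT_EF, a
load-dependent perceptual bias in the match phase, and EMG driven by two
ground-truth muscle synergies (an elbow flexion/extension synergy and a
shoulder abduction synergy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Surface-EMG channel order used throughout the package.
MUSCLES = ("BIC", "TRI", "AntDel", "MedDel", "PosDel", "PEC", "TrapM", "TrapU")

N_MUSCLES = len(MUSCLES)


def default_ground_truth_w() -> np.ndarray:
    """Default 8 x 2 ground-truth synergy matrix (unit-norm columns).

    Column 0 loads the elbow flexor/extensor pair (BIC, TRI); column 1
    loads the shoulder abductor group (AntDel, MedDel, PosDel, PEC,
    TrapM, TrapU).
    """
    w = np.zeros((N_MUSCLES, 2))
    w[MUSCLES.index("BIC"), 0] = 0.80
    w[MUSCLES.index("TRI"), 0] = 0.60
    shoulder = {"AntDel": 0.55, "MedDel": 0.55, "PosDel": 0.35,
                "PEC": 0.30, "TrapM": 0.30, "TrapU": 0.25}
    for name, val in shoulder.items():
        w[MUSCLES.index(name), 1] = val
    return w / np.linalg.norm(w, axis=0, keepdims=True)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic torque-matching cohort generator.

    Units are noted per field; load fractions are relative to MVT_SABD
    (maximum voluntary shoulder abduction torque) and the elbow target is
    a fraction of MVT_EF (maximum voluntary elbow flexion torque).
    """

    n_participants: int = 10
    seed: int = 0
    sample_rate: float = 1000.0  # Hz
    mvt_ef_mean: float = 48.7    # Nm
    mvt_ef_sd: float = 18.3      # Nm
    mvt_sabd_mean: float = 54.5  # Nm
    mvt_sabd_sd: float = 24.0    # Nm
    loads: tuple[float, ...] = (0.10, 0.30, 0.50)
    elbow_target: float = 0.25           # fraction of MVT_EF
    accept_band: float = 0.05            # +/- fraction around targets
    trials_per_block: int = 10           # first n_practice flagged practice
    n_practice: int = 2
    ce_bias_per_load: tuple[float, ...] = (0.34, 1.85, 3.77)  # Nm
    match_noise_sd: float = 2.0          # Nm, per-trial match-level noise
    torque_hold_cv: float = 1.5          # % of held torque, within-hold noise
    tref_mean_per_load: tuple[float, ...] = (6.44, 3.86, 3.65)  # s
    tref_sd_per_load: tuple[float, ...] = (2.22, 1.24, 1.69)    # s
    ground_truth_w: np.ndarray = field(default_factory=default_ground_truth_w)
    emg_line_noise_amp: float = 0.05     # 60 Hz amplitude, relative to MVC RMS
    emg_noise_floor: float = 0.02        # broadband floor, relative to MVC RMS
    elbow_load_coupling: float = 0.0     # elbow-drive increase per unit load
    activation_trial_cv: float = 0.15    # trial-to-trial synergy gain SD
    synthesize_emg: bool = True          # torque-only cohorts for large-n runs
    # timeline constants (s); cue jitter is truncated at min_interval
    up_time: float = 0.5
    shoulder_ramp: float = 1.5
    shoulder_settle: float = 1.0
    hold_duration: float = 1.0
    ref_to_match_gap: float = 6.0
    match_rise_mean: float = 2.5
    match_rise_sd: float = 0.8
    min_interval: float = 0.5
    tail: float = 0.5

    def __post_init__(self) -> None:
        self.ground_truth_w = np.asarray(self.ground_truth_w, dtype=float)
        self.validate()

    def validate(self) -> None:
        """Raise ValueError naming the first invalid parameter."""
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("mvt_ef_sd", "mvt_sabd_sd", "match_noise_sd",
                     "torque_hold_cv", "emg_line_noise_amp",
                     "emg_noise_floor", "match_rise_sd",
                     "elbow_load_coupling", "activation_trial_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not all(0.0 < l < 1.0 for l in self.loads):
            raise ValueError("loads must lie in (0, 1)")
        if not 0.0 < self.elbow_target < 1.0:
            raise ValueError("elbow_target must lie in (0, 1)")
        if self.accept_band <= 0:
            raise ValueError("accept_band must be > 0")
        if self.trials_per_block <= self.n_practice:
            raise ValueError("trials_per_block must exceed n_practice")
        n_loads = len(self.loads)
        for name in ("ce_bias_per_load", "tref_mean_per_load",
                     "tref_sd_per_load"):
            if len(getattr(self, name)) != n_loads:
                raise ValueError(f"{name} must have one entry per load")
        if any(sd < 0 for sd in self.tref_sd_per_load):
            raise ValueError("tref_sd_per_load entries must be >= 0")
        w = self.ground_truth_w
        if w.ndim != 2 or w.shape[0] != N_MUSCLES:
            raise ValueError(f"ground_truth_w must be {N_MUSCLES} x k")
        if np.any(w < 0):
            raise ValueError("ground_truth_w must be nonnegative")
        if np.any(np.linalg.norm(w, axis=0) == 0):
            raise ValueError("ground_truth_w columns must be nonzero")

    @property
    def n_analyzed(self) -> int:
        """Non-practice trials per block."""
        return self.trials_per_block - self.n_practice
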