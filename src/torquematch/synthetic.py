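"""Synthetic torque-matching cohorts with known ground truth.

Each generated trial follows the two-phase protocol: the participant
abducts the shoulder to a load-specific torque ("up"), flexes the elbow to
25 % MVT_EF under visual feedback ("in"), stabilizes and memorizes the
torque ("hold"), relaxes, and six seconds later reproduces the torque
from memory without feedback ("match" ... "hold" ... "relax").  Cue times
are stored as exact metadata; downstream code never detects events.

Ground truth injected per trial and recoverable by the pipeline:

* the match-phase constant error (``ce_bias_per_load`` plus Gaussian
  trial-to-trial noise ``match_noise_sd``),
* the within-hold torque coefficient of variation ``torque_hold_cv``,
* the time-to-stabilize distribution ``tref_mean_per_load``,
* the synergy structure ``ground_truth_w`` driving all eight EMG channels.

Raw EMG is amplitude-modulated band-limited (20-450 Hz) Gaussian noise —
the modulation envelope is ``W @ h(t)`` — plus a 60 Hz line component and
a broadband noise floor, so the full preprocessing chain (low-pass, notch,
rectification, RMS smoothing, MVC normalization) is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from torquematch.config import MUSCLES, N_MUSCLES, GeneratorConfig

# activation drive (fraction of MVC at full task intensity) for the
# elbow-flexion synergy and the shoulder-abduction synergy
_ELBOW_DRIVE = 0.8
_SHOULDER_DRIVE = 0.7


@dataclass
class ParticipantReference:
    """Per-participant normalization constants.

    ``mvc_emg_peak`` is the peak rectified-and-smoothed EMG envelope per
    muscle during a maximum voluntary contraction, in raw signal units;
    envelopes are expressed in percent of it.
    """

    participant_id: str
    mvt_ef: float
    mvt_sabd: float
    mvc_emg_peak: np.ndarray  # (8,) strictly positive

    def __post_init__(self) -> None:
        self.mvc_emg_peak = np.asarray(self.mvc_emg_peak, dtype=float)
        if self.mvt_ef <= 0 or self.mvt_sabd <= 0:
            raise ValueError("MVT values must be strictly positive")
        if self.mvc_emg_peak.shape != (N_MUSCLES,) or np.any(
            self.mvc_emg_peak <= 0
        ):
            raise ValueError("mvc_emg_peak must be 8 strictly positive values")


@dataclass
class TrialRecording:
    """One trial's torque and EMG time series with cue-event metadata."""

    participant_id: str
    load_condition: float        # fraction of MVT_SABD
    trial_index: int
    is_practice: bool
    sample_rate: float
    elbow_torque: np.ndarray     # Nm, (T,)
    shoulder_torque: np.ndarray  # Nm, (T,)
    emg: np.ndarray | None       # raw signal, (8, T); None if not synthesized
    events: dict[str, float]     # cue name -> time (s)
    truth: dict | None = field(default=None, repr=False)

    EVENT_ORDER = ("up", "in", "hold_ref", "relax_ref",
                   "match", "hold_match", "relax_end")

    def __post_init__(self) -> None:
        n = len(self.elbow_torque)
        if len(self.shoulder_torque) != n:
            raise ValueError("torque series must share length")
        if self.emg is not None and self.emg.shape != (N_MUSCLES, n):
            raise ValueError("emg must be (8, T) matching torque length")
        duration = n / self.sample_rate
        times = [self.events[k] for k in self.EVENT_ORDER]
        if not all(0.0 <= t <= duration for t in times):
            raise ValueError("event times must lie within the recording")
        if not all(a < b for a, b in zip(times, times[1:])):
            raise ValueError("events must be strictly ordered "
                             f"{' < '.join(self.EVENT_ORDER)}")

    @property
    def duration(self) -> float:
        return len(self.elbow_torque) / self.sample_rate


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float) -> float:
    if sd == 0:
        return max(mean, low)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= low:
            return x
    return low


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """C1 ramp from 0 at t0 to 1 at t1, clamped outside."""
    u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _band_limited_noise(rng: np.random.Generator, n: int,
                        sample_rate: float) -> np.ndarray:
    """Zero-mean unit-RMS Gaussian noise band-limited to 20-450 Hz."""
    high = min(450.0, 0.49 * sample_rate)
    sos = sps.butter(4, [20.0, high], btype="bandpass",
                     fs=sample_rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _synthesize_emg(rng: np.random.Generator, envelope: np.ndarray,
                    gains: np.ndarray, time: np.ndarray,
                    sample_rate: float, line_amp: float,
                    floor: float) -> np.ndarray:
    """Raw EMG = gain * (envelope-modulated carrier + 60 Hz line + floor)."""
    n = len(time)
    raw = np.empty((N_MUSCLES, n))
    for m in range(N_MUSCLES):
        carrier = _band_limited_noise(rng, n, sample_rate)
        phase = rng.uniform(0, 2 * np.pi)
        line = line_amp * np.sin(2 * np.pi * 60.0 * time + phase)
        noise = floor * rng.standard_normal(n)
        raw[m] = gains[m] * (envelope[m] * carrier + line + noise)
    return raw


def synergy_activations(elbow_torque: np.ndarray,
                        shoulder_torque: np.ndarray,
                        ref: ParticipantReference,
                        n_synergies: int,
                        elbow_load_coupling: float = 0.0,
                        trial_gains: np.ndarray | None = None) -> np.ndarray:
    """Programmed activation time courses h(t), one row per synergy.

    The first synergy is driven by the elbow flexion torque, the
    remaining ones by the shoulder abduction torque (so with the default
    two-column ``ground_truth_w`` the shoulder synergy tracks the load in
    the reference phase and is near zero in the match phase).  The elbow
    drive rises with the concurrent shoulder load
    (``elbow_load_coupling``), mirroring the extra elbow-muscle activity
    observed when flexing under an abduction load; ``trial_gains``
    applies a per-synergy multiplicative gain emulating trial-to-trial
    EMG amplitude variability at matched torque.
    """
    shoulder_frac = np.clip(shoulder_torque, 0, None) / ref.mvt_sabd
    h = np.zeros((n_synergies, len(elbow_torque)))
    h[0] = (_ELBOW_DRIVE * np.clip(elbow_torque, 0, None) / ref.mvt_ef
            * (1.0 + elbow_load_coupling * shoulder_frac))
    for j in range(1, n_synergies):
        h[j] = _SHOULDER_DRIVE * shoulder_frac
    if trial_gains is not None:
        h *= np.asarray(trial_gains)[:, None]
    return h


def generate_trial(ref: ParticipantReference, load: float, bias: float,
                   seed: int, config: GeneratorConfig | None = None, *,
                   load_index: int | None = None, trial_index: int = 0,
                   is_practice: bool = False,
                   emg_gains: np.ndarray | None = None) -> TrialRecording:
    """Generate one torque-matching trial.

    ``bias`` is the constant error injected into the match phase (Nm);
    the realized match level additionally receives one Gaussian draw of
    SD ``config.match_noise_sd``.  Practice trials double both noise
    sources.  Identical arguments yield identical trials.
    """
    cfg = config if config is not None else GeneratorConfig()
    if not 0.0 < load < 1.0:
        raise ValueError("load must lie in (0, 1)")
    if load_index is None:
        load_index = int(np.argmin(np.abs(np.asarray(cfg.loads) - load)))
    rng = np.random.default_rng(seed)
    noise_mult = 2.0 if is_practice else 1.0
    fs = cfg.sample_rate

    # --- cue timeline (snapped to the sampling grid) ----------------------
    def snap(t: float) -> float:
        return round(t * fs) / fs

    t_up = snap(cfg.up_time)
    t_in = snap(t_up + cfg.shoulder_ramp + cfg.shoulder_settle)
    tref = _truncated_normal(rng, cfg.tref_mean_per_load[load_index],
                             cfg.tref_sd_per_load[load_index],
                             cfg.min_interval)
    t_hold_ref = snap(t_in + tref)
    tref = t_hold_ref - t_in
    t_relax_ref = snap(t_hold_ref + cfg.hold_duration)
    t_match = snap(t_relax_ref + cfg.ref_to_match_gap)
    rise = _truncated_normal(rng, cfg.match_rise_mean, cfg.match_rise_sd,
                             cfg.min_interval)
    # the matched torque plateaus 0.5 s before the participant voices
    # "target", so the +/-0.25 s analysis window sits fully on the plateau
    t_plateau = snap(t_match + rise)
    t_hold_match = snap(t_plateau + 0.5)
    t_relax_end = snap(t_hold_match + cfg.hold_duration)
    duration = t_relax_end + cfg.tail
    n = int(round(duration * fs))
    time = np.arange(n) / fs

    # --- elbow torque -----------------------------------------------------
    target = cfg.elbow_target * ref.mvt_ef
    match_level = target + bias + rng.normal(0.0, cfg.match_noise_sd
                                             * noise_mult)
    match_level = max(match_level, 0.1 * target)
    elbow = target * _smoothstep(time, t_in, t_hold_ref)
    elbow *= 1.0 - _smoothstep(time, t_relax_ref, t_relax_ref + 0.8)
    elbow += match_level * (_smoothstep(time, t_match, t_plateau)
                            - _smoothstep(time, t_relax_end, duration))

    # --- shoulder torque --------------------------------------------------
    level_ref = load * ref.mvt_sabd
    # residual shoulder activity in the match phase, well under the 10 %
    # MVT_SABD abort threshold the protocol enforces
    level_match = rng.uniform(0.01, 0.05) * ref.mvt_sabd
    shoulder = level_ref * _smoothstep(time, t_up, t_up + cfg.shoulder_ramp)
    drop = _smoothstep(time, t_relax_ref, t_relax_ref + 1.5)
    shoulder = shoulder * (1 - drop) + level_match * drop
    shoulder *= 1.0 - _smoothstep(time, t_relax_end, duration)

    # --- multiplicative hold noise (CV of the held torque) ----------------
    cv = cfg.torque_hold_cv / 100.0 * noise_mult
    if cv > 0:
        elbow = elbow * (1.0 + cv * rng.standard_normal(n))
        shoulder = shoulder * (1.0 + cv * rng.standard_normal(n))

    events = {"up": t_up, "in": t_in, "hold_ref": t_hold_ref,
              "relax_ref": t_relax_ref, "match": t_match,
              "hold_match": t_hold_match, "relax_end": t_relax_end}

    # --- EMG --------------------------------------------------------------
    emg = None
    truth: dict = {"match_level": match_level, "tref": tref, "bias": bias}
    if cfg.synthesize_emg:
        w = cfg.ground_truth_w
        trial_gains = np.clip(
            1.0 + cfg.activation_trial_cv * noise_mult
            * rng.standard_normal(w.shape[1]), 0.1, None)
        h = synergy_activations(elbow, shoulder, ref, w.shape[1],
                                cfg.elbow_load_coupling, trial_gains)
        envelope = w @ h
        gains = emg_gains if emg_gains is not None else np.ones(N_MUSCLES)
        emg = _synthesize_emg(rng, envelope, gains, time, fs,
                              cfg.emg_line_noise_amp * noise_mult,
                              cfg.emg_noise_floor * noise_mult)
        truth["activation_envelope"] = envelope
        truth["h"] = h

    return TrialRecording(
        participant_id=ref.participant_id, load_condition=load,
        trial_index=trial_index, is_practice=is_practice, sample_rate=fs,
        elbow_torque=elbow, shoulder_torque=shoulder, emg=emg,
        events=events, truth=truth,
    )


def _mvc_peak_envelope(rng: np.random.Generator, gains: np.ndarray,
                       cfg: GeneratorConfig) -> np.ndarray:
    """Peak processed envelope per muscle from a simulated 2 s MVC burst.

    Runs the same preprocessing chain the pipeline applies (minus the
    normalization step itself), so percent-MVC envelopes are
    self-consistent with the task recordings.
    """
    from torquematch.emg import lowpass_filter, notch_filter, rectify, \
        rms_envelope

    fs = cfg.sample_rate
    n = int(round(2.0 * fs))
    time = np.arange(n) / fs
    env = np.ones((N_MUSCLES, n))  # full activation
    raw = _synthesize_emg(rng, env, gains, time, fs,
                          cfg.emg_line_noise_amp, cfg.emg_noise_floor)
    peaks = np.empty(N_MUSCLES)
    for m in range(N_MUSCLES):
        x = lowpass_filter(raw[m], 250.0, fs)
        x = notch_filter(x, 60.0, fs)
        x = rms_envelope(rectify(x), 0.25, fs)
        peaks[m] = x.max()
    return peaks


def generate_participant(participant_id: str, seed: int,
                         config: GeneratorConfig | None = None
                         ) -> tuple[ParticipantReference,
                                    list[TrialRecording]]:
    """Generate one participant: reference values plus all trial blocks."""
    cfg = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(seed)
    mvt_ef = _truncated_normal(rng, cfg.mvt_ef_mean, cfg.mvt_ef_sd, 10.0)
    mvt_sabd = _truncated_normal(rng, cfg.mvt_sabd_mean, cfg.mvt_sabd_sd,
                                 10.0)
    gains = rng.uniform(0.5, 1.5, N_MUSCLES)  # electrode/tissue scale factors
    ref = ParticipantReference(participant_id=participant_id,
                               mvt_ef=mvt_ef, mvt_sabd=mvt_sabd,
                               mvc_emg_peak=gains)  # placeholder, see below
    if cfg.synthesize_emg:
        ref.mvc_emg_peak = _mvc_peak_envelope(rng, gains, cfg)
    trials = []
    for load_index, load in enumerate(cfg.loads):
        bias = cfg.ce_bias_per_load[load_index]
        for trial_index in range(cfg.trials_per_block):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trials.append(generate_trial(
                ref, load, bias, trial_seed, cfg, load_index=load_index,
                trial_index=trial_index,
                is_practice=trial_index < cfg.n_practice,
                emg_gains=gains,
            ))
    return ref, trials


def generate_cohort(config: GeneratorConfig
                    ) -> list[tuple[ParticipantReference,
                                    list[TrialRecording]]]:
    """Generate a full cohort; identical config (incl. seed) -> identical
    output."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_participants) % (2**31 - 1)
    cohort = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        cohort.append(generate_participant(pid, int(seeds[i]), config))
    return cohort
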