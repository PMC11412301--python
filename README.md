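# torquematch

Analysis pipeline for multi-joint isometric **torque-matching
psychophysics**: how features of torque generation at the elbow —
force steadiness, elbow flexor/extensor coactivation, time to stabilize,
and the underlying muscle synergies — relate to how accurately a person
perceives and reproduces a self-generated elbow torque while the shoulder
simultaneously carries an abduction load.

It is written for motor-control and EMG researchers who run (or want to
model) two-phase matching protocols: a *reference* phase where the
participant produces 25 % of their maximal elbow-flexion torque
(MVT_EF) under visual feedback while abducting the shoulder to 10, 30 or
50 % of maximal abduction torque (MVT_SABD), and a feedback-free *match*
phase where the remembered torque is reproduced. Because studies of this
kind rarely deposit raw recordings, the package ships a synthetic-data
generator that emulates the full protocol — cue timeline, torque
profiles, 8-channel surface EMG with line noise — with known ground
truth, so every stage of the analysis is testable end to end.

## What it computes

For each trial, with τ the elbow torque averaged over a 0.5 s analysis
window (after the reference-phase "hold" cue, or ±0.25 s around the
match-phase "hold" cue):

- **Matching error** τ_err = τ_match − τ_reference; per participant and
  load, the **constant error** CE = mean(τ_err) (accuracy) and
  **variable error** VE = SD(τ_err) (precision).
- **Force steadiness** CV = SD/mean × 100 % of the held reference torque.
- **Coactivation** = EMG_TRI / (EMG_BIC + EMG_TRI) × 100 %, from
  MVC-normalized envelopes (250 Hz low-pass, 60 Hz notch, rectification,
  250 ms RMS window, normalization to the MVC peak envelope).
- **T_ref**, the time from the "in" cue to torque stabilization.
- **Muscle synergies**: each participant's 8 × 48 matrix *A* of
  phase-averaged envelopes (8 muscles × 2 phases × 8 trials × 3 loads),
  row-normalized to max 1 and unit variance, is factorized as
  *A* ≈ *W H* by nonnegative matrix factorization; the synergy count *n*
  is the smallest with VAF = 1 − ‖A − WH‖²_F / ‖A‖²_F ≥ 0.95. Synergies
  are compared across participants against the 95th percentile of the
  10⁶ pairwise scalar products of 1000 random unit synergies, and
  matched greedily to a reference participant.
- **Spearman rank correlations** (exact permutation p-values for n ≤ 8)
  between CV / coactivation / T_ref and τ_err, per participant and load.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
simulated 10-participant cohort:

```sh
python analysis/01_simulate.py        # writes results/cohort/
python analysis/02_trial_features.py
python analysis/03_perception.py
python analysis/04_synergies.py
python analysis/05_correlations.py
```

Output from a run with the default seed:

```
300 trials, 240 valid -> results/trial_features.tsv
  load 10%: CV 1.50% | coactivation 42.0% | T_ref 6.55 s
  load 30%: CV 1.50% | coactivation 42.3% | T_ref 4.04 s
  load 50%: CV 1.51% | coactivation 42.2% | T_ref 3.95 s
30 participant x load cells -> results/perception.tsv
  load 10%: CE +0.62 +/- 0.63 Nm | VE 1.89 Nm
  load 30%: CE +1.77 +/- 0.72 Nm | VE 1.71 Nm
  load 50%: CE +3.48 +/- 0.72 Nm | VE 2.04 Nm
synergy counts: [2, 2, 2, 2, 2, 2, 2, 2, 2, 2]
selected-model VAF: mean 99.9%, min 99.9%
similarity threshold 0.918; matched per reference synergy: [10, 10]
significant at p<0.05: 3/90 (3.3%)
```

Reading this: 60 of 300 trials are practice and excluded; the held
torque is steady (CV ≈ 1.5 %, the generator's injected value); CE rises
with the shoulder load, recovering the injected load-dependent
perceptual bias (0.34 / 1.85 / 3.77 Nm) within sampling error while VE
stays near the injected 2 Nm match noise; the VAF ≥ 95 % rule selects
two synergies per participant — the generator's elbow and shoulder
ground-truth synergies — and all are shared across participants above
the 0.918 random-similarity threshold; and, since generation features
are independent of τ_err by construction, significant correlations
appear at roughly the 5 % false-positive rate.

The same stages are available as a CLI
(`torquematch simulate | analyze | report`) or as library calls; see the
module docstrings under `src/torquematch/`.

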