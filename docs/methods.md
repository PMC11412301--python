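# Methods

This note documents the models, numerical conventions and design
choices behind the package, and what the synthetic cohorts do and do not
establish about real recordings.

## Protocol model

A trial is a cue-driven sequence
`up < in < hold_ref < relax_ref < match < hold_match < relax_end`.
Between "up" and "in" the shoulder abducts to one of three loads (10,
30, 50 % MVT_SABD, ±5 % acceptance band); between "in" and the
reference "hold" cue the elbow ramps to 25 % MVT_EF (T_ref, the
stabilization time); the torque is then held for ≥ 1 s, the arm relaxes,
and 6 s later the remembered torque is reproduced without feedback. A
match-phase shoulder torque at or above 10 % MVT_SABD invalidates the
trial, as do missing cues and practice status (the first 2 of each
10-trial block). Cue times are metadata, not detected from signals, and
are snapped to the 1 kHz sampling grid so analysis windows align exactly
with samples.

Analysis windows are half-open `[start, end)` with the start index
floored to the sample grid: 0.5 s after `hold_ref` for the reference
quantities, `hold_match` ± 0.25 s for the matched torque. CV and VE use
the sample SD (n − 1); τ_err = τ_match − τ_reference holds exactly by
construction.

One protocol ambiguity is worth noting: T_ref can be read either as the
"in"→"hold" interval or as the "in"→"relax" interval (which would add
the 1 s hold). The package implements the former; the choice only
shifts T_ref by a constant.

## Synthetic cohorts

The generator's defaults are the study conditions the analysis assumes:
MVT_EF ~ 48.7 ± 18.3 Nm and MVT_SABD ~ 54.5 ± 24.0 Nm across
participants (truncated at 10 Nm), T_ref means 6.44 / 3.86 / 3.65 s
(SDs 2.22 / 1.24 / 1.69 s, truncated at 0.5 s) for the three loads,
match-phase constant-error bias 0.34 / 1.85 / 3.77 Nm plus Gaussian
trial-level noise of SD 2 Nm, and a within-hold torque CV of 1.5 %
(multiplicative white noise on the held plateau). Practice trials double
both noise sources. Torque profiles are smoothstep ramps between
plateaus; the matched torque plateaus 0.5 s before the `hold_match` cue
so the analysis window sits fully on the plateau. Inter-cue intervals
not pinned down by the protocol (pre-"up" lead-in, shoulder ramp and
settle, match-phase rise time) are declared defaults, chosen to produce
~20 s trials.

Raw EMG per channel is amplitude-modulated carrier noise:
`gain_m · (envelope_m(t) · carrier(t) + line + floor)`, where the
carrier is unit-RMS Gaussian noise band-limited to 20–450 Hz (the
hardware band of typical surface-EMG amplifiers), `line` is a 60 Hz
sinusoid (relative amplitude 0.05 by default) and `floor` broadband
noise (0.02). The modulation envelope is `W h(t)` with `W` the 8 × 2
ground-truth synergy matrix (unit-norm columns: BIC/TRI for the elbow
synergy; the six shoulder muscles for the abduction synergy) and `h(t)`
driven by the instantaneous torques — the elbow component tracks elbow
torque in both phases, the shoulder component tracks shoulder torque, so
it scales with load in the reference phase and is near zero during
matching. Each synergy's drive additionally receives a per-trial
multiplicative gain of CV 15 %, representing the trial-to-trial EMG
amplitude variability seen at matched torque in real recordings; without
it the elbow synergy's activation would be nearly constant across the
48 matrix cells, a degenerate condition under which any single component
close to the column-mean direction reaches 95 % uncentered VAF. An
optional `elbow_load_coupling` lets the elbow drive rise with the
concurrent shoulder load (as elbow-muscle activity does empirically);
it defaults to off because it correlates the two activations and
thereby weakens synergy identifiability. MVC normalization constants are
produced by simulating a 2 s maximal contraction per muscle and passing
it through the same preprocessing chain, so percent-MVC values are
self-consistent.

What the generator does **not** model: biomechanical coupling between
joints (torques are prescribed, not computed from muscle forces),
motor-unit structure in the EMG (the carrier is Gaussian), fatigue or
learning across trials, and event-detection uncertainty. Passing tests
therefore show that the analysis recovers known parameters from signals
with the right first- and second-order structure — not that it is robust
to every artifact of real recordings.

## EMG preprocessing

Filter families are standard choices: 4th-order Butterworth low-pass at
250 Hz and a Q = 30 IIR notch at 60 Hz, both applied forward–backward
(zero phase, effective 8th/4th order). The RMS envelope uses a centered
250 ms window truncated at the edges, keeping the envelope delay-free
and length-preserving. Envelopes are reported in percent of the MVC peak
envelope. Tests assert frequency-response behaviour (DC gain, pass/stop
band, notch depth), not coefficient values, so the filter family could
be swapped without invalidating the oracle.

## Synergy decomposition

NMF minimizes ‖A − WH‖²_F with Lee–Seung multiplicative updates,
20 random restarts (seeded via a spawned sequence, so results are
reproducible and restart-independent of call order), tol 1e-6 on the
relative objective change, max 2000 iterations; the best restart is
kept and W columns are unit-normalized with the scale folded into H.
VAF is uncentered (1 − SSE/‖A‖²_F), the dominant convention for synergy
model selection; a centered variant is provided for sensitivity
analyses. Model selection fits n = 1…8 in order and stops at the first
n with VAF ≥ 0.95; if none reaches it the full model is returned with a
flag.

The random-synergy similarity null draws coordinates Uniform(0, 1) and
normalizes to unit Euclidean norm — nonnegative and unbiased within the
positive orthant — and uses **all ordered pairs including self-pairs**
(n² = 10⁶ values at n = 1000). Self-pairs contribute 0.1 % of the mass
at exactly 1.0 and shift the 95th percentile negligibly; a flag excludes
them for sensitivity checks. Cross-participant matching is greedy
best-first against one reference participant (each reference synergy
used at most once per participant), reflecting pairwise comparison
against a single reference; ties at equal similarity resolve by
column index. Group-mean synergies average matched vectors including
the reference's. When comparing fitted synergies with the generator's
ground truth, the truth must be carried into the normalized matrix
space (divide rows by the recorded row scales, renormalize columns):
the factorization lives in that space, and cosines against the raw
ground truth conflate row scaling with recovery error.

## Statistics

Spearman's rho is the Pearson correlation of mid-ranks. For n ≤ 8 the
two-sided p-value is exact: all n! permutations are enumerated
(vectorized; for tie-free data the null distribution depends only on n
and is cached), counting |rho| ≥ |rho_obs| with a 1e-12 guard against
floating-point ties. For larger n the usual t-approximation with
n − 2 degrees of freedom is used. Mixed-effects inference across loads
is deliberately out of scope; the pipeline exports tidy TSVs
(`trial_features.tsv`, `perception.tsv`, `correlations.tsv`) that any
stats environment can consume.

## Problem sizes and tolerances

Default analysis cohorts use 10 participants × 3 loads × 10 trials;
property tests that need tighter sampling error use torque-only
generation (no EMG synthesis) at up to 50 participants or 200 trials
per load. Stochastic recovery tests use 3-SE bands derived from the
generator's known noise parameters rather than empirical SEs, which are
unstable at small cohort sizes. Degenerate inputs are rejected with
named-parameter messages: zero/constant activity-matrix rows, empty
error lists, constant correlation vectors, non-positive MVC peaks,
out-of-range filter frequencies.

## Known limitations

- The generator's CE/VE/T_ref defaults are emulation targets, not
  claims; recovering them shows pipeline correctness, not agreement
  with any particular population.
- NMF identifiability on real matrices depends on activation diversity;
  with near-collinear activations the selected count is still correct
  but individual synergy vectors can mix (see the coupling discussion
  above).
- The exact Spearman p assumes exchangeability across trials; serial
  correlation between consecutive trials would invalidate it, and the
  generator produces none.
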