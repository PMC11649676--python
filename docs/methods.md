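# Methods

This note documents the models, defaults and numerical choices behind
`eegdta`, and what the synthetic-data experiments do and do not establish.

## Synthetic session model

The generator emulates a cue-based (Graz-paradigm) session: a 15 s setup
wait, then per trial a 4 s fixation-cross baseline, a 1 s directional arrow,
movement (or imagery) at arrow offset, and a 4 s inter-trial period; 18 s
trials, 32 channels on a standard 10–20 montage, 500 Hz sampling, left and
right trials balanced and shuffled by the session seed.

Each channel is a sum of independent components, each drawn from its own
seeded random stream whose draws do not depend on any amplitude parameter —
so the signal is exactly linear in the amplitudes (doubling all of them with
the same seed doubles the output bit for bit), and setting the MRCP peak and
ERD depth to zero yields a class-free null session.

**MRCP.** The literature specifies onsets, not waveforms: an early
low-amplitude readiness component from ~1.5 s before movement and a steeper
late component from ~0.5 s. We use a two-slope piecewise ramp with
half-cosine corner smoothing through the knots (0 at −1.5 s,
`early_fraction × peak` = 0.2 × −8 µV at −0.5 s, −8 µV at movement onset,
recovery to 0 over 0.5 s). The cosine segments keep the waveform continuous,
monotone between knots and smooth enough for FIR filtering tests. A cued
paradigm strictly elicits a contingent negative variation rather than a
self-paced readiness potential; the two are treated as one configurable
pre-movement negativity because the detection pipeline is identical for
both. Spatial gain is a Gaussian falloff from Cz (σ = 0.75 head units,
giving 0.8 at C3/C4) with the hemisphere ipsilateral to the moving arm
down-weighted by 0.8. The peak of −8 µV is literature-typical, not a fit to
any particular cohort, and fully configurable.

**ERD.** Mu (8–12 Hz) and beta (13–30 Hz, half amplitude) carriers are
seeded band-limited Gaussian noise per channel, centered on sensorimotor
sites, multiplied by an envelope that descends from 1 to `1 − erd_depth`
(default 0.4) between 1.5 s before movement and movement onset, holds
briefly, and recovers; the ipsilateral hemisphere desynchronizes by
`depth / laterality` (laterality 1.5). Stochastic-phase carriers matter:
fixed-phase sinusoids on a strictly periodic trial grid would place
cue-relative phases on a deterministic lattice that a flexible classifier
can exploit even with zero ERD depth — an information leak real EEG does
not have, and one the zero-effect invariant explicitly guards against.

**Noise and artifacts.** Per-channel 1/f ("pink") noise (default SD 4 µV)
plus a 30% spatially shared pink component; common-phase 50 Hz mains at
2 µV; frontal-weighted 0.3 s biphasic blinks (2/min, 80 µV); band-limited
(20–100 Hz) EMG bursts on temporal channels (1/min, 20 µV). These give the
ICA stage realistic, high-amplitude targets. The generator does not attempt
biophysical forward modeling, electrode drift, non-stationary rhythms or
cross-trial MRCP variability — so passing recovery tests on synthetic data
demonstrates that the pipeline's machinery is correct, not that any given
accuracy will transfer to recorded EEG.

## Conditioning chain

Fixed order: high-pass → notch → common average reference → ICA → epoching.

* High-pass: windowed-sinc (Hamming) FIR at 0.1 Hz, transition width equal
  to the cutoff (16,501 taps at 500 Hz). "One-pass, zero-phase" is realized
  as a single forward pass of the odd, symmetric kernel with the group delay
  compensated by centering — not forward-backward filtering. A configurable
  `max_filter_length` cap trades transition width for kernel length with a
  logged warning (used for per-epoch timing, where a 33 s kernel cannot
  apply to a 1 s window).
* Notch: band-stop FIR, 2 Hz stop band around 50 Hz, 1 Hz transitions
  (1,651 taps); ≥ 20 dB at 50 Hz, within ±1 dB at ±5 Hz.
* ICA: FastICA on all 32 components, seeded. Rejection is a documented
  heuristic, not a reproduction of any published criterion: a component is
  removed when its kurtosis z-score across components exceeds 3 or its
  absolute correlation with a frontal (Fp) channel exceeds 0.8 — thresholds
  chosen to catch only blatant blink/EMG components and to be a no-op on
  artifact-free data. Removing more than half the components raises a
  warning.
* Epoching: half-open sample windows, label 1 for `[cue, cue+1 s)`, label 0
  for `[cue−1 s, cue)`; at lag ℓ the positive window becomes
  `[cue−ℓ, cue−ℓ+1 s)` and keeps label 1 (the MRCP extends ~1.5 s before
  movement, so for ℓ ≤ 1 with a 1 s arrow the window remains inside the
  anticipation period). Negative windows are not slid: on slid positive-only
  window sets, TPR and accuracy coincide. Epochs overlapping the
  filter-edge margin are rejected with a warning.

## Classifiers

The four network families are built from an in-package NumPy layer library
(dense, valid stride-1 Conv2D, max pooling with stride equal to pool size,
single LSTM returning its last hidden state) with exact backpropagation —
gradients are verified against finite differences in the test suite. Layer
stacks follow the reference definitions exactly; the LSTM's ReLU activation is an
explicit override of the customary tanh. Pooling stride equals pool size
(the framework-default convention; stride-1 pooling would leave a ~10⁵-way
flatten inconsistent with the architectures' size). Epochs enter the
convolutional families as a single-plane channels × samples image (32 × 500)
and the MLP flattened.

Training: Adam (lr 10⁻³) on binary cross-entropy, batch size 8, up to 100
epochs with early stopping on validation loss (patience 10), stratified 20%
validation split, per-channel z-scoring with training-set statistics, all
seeded through `random_state`. These last three items (scaling, epochs,
batch size) are package choices sized for ~10²-example datasets.

The matched-filter family: the effect-matched spatial filter weight of
channel *c* is ⟨d_c, g⟩ where d_c is the channel's mean class-difference
waveform and g the first principal time-course (SVD) of the difference
matrix, unit-normalized — an interpretation of the effect-matched idea,
togglable to a simpler RMS weighting. The template is the mean
positive-class surrogate waveform of the training split; the single feature
per epoch is its Pearson correlation with the template; LDA thresholds it.

Degenerate cases: single-class training data and zero class effect raise;
precision/F1 with zero predicted positives are reported as 0 with an
explicit flag, never NaN. The decision threshold is fixed at probability
0.5; ROC sweeping is out of scope.

## DTA, CTD, TTA

Lag is how much earlier the 1 s window starts relative to its training
position, anchored to the cue (movement follows the cue by the 1 s arrow).
The TPR-over-lag grid (0 to 1 s, 0.1 s steps) is interpolated with PCHIP —
shape-preserving, no overshoot between knots — and the sustained-crossing
rule is evaluated on a dense 1 ms grid, not only at knots: DTA_k is the last
grid point before the interpolant first drops below k/100. Dropping below k
at lag 0 gives status `undefined` (printed `–`); never dropping gives
`censored_at_grid_max` (printed `>1,000`).

CIs are percentile bootstrap over trials (default 1,000 replicates, seeded):
resample per-trial outcome rows, rebuild the profile, re-estimate. Censored
replicates enter the percentiles at the 1,000 ms cap and undefined ones at
0 ms; the interval is widened, if needed, to contain the point estimate.
A Gaussian-process alternative for interval construction was considered and
not implemented; the bootstrap is simpler and directly tied to trial
resampling.

Lag profiles are computed on held-out trials when the caller provides a
subset, otherwise on all trials. This matters: with in-sample profiles,
small training sets *lengthen* the apparent DTA (memorized trials keep TPR
high at large lags), whereas on independent trials fewer training examples
shorten it, as expected; the small-sample contrast in the test suite
therefore profiles on a separate evaluation session.

CTD is measured wall-clock per epoch (preprocessing + inference,
`time.perf_counter`) and is hardware-specific by contract — it is never
asserted against external timing values. TTA = DTA − CTD and may be
negative; it is only defined for an estimated (non-censored) DTA.

## Statistics

Families are compared on accuracy with the two-sided Mann-Whitney U test:
exact null distribution for tie-free samples with n_a·n_b ≤ 400, otherwise
the tie-corrected normal approximation; α = 0.05; no multiplicity
correction by default (an optional Holm adjustment is available). Runs are
pooled per family across seeds.

## Problem sizes in the test and acceptance runs

The packaged experiments use sizes chosen to exercise every code path at
desk scale: 64-trial sessions for signal-recovery and generator-consistency
checks (10 and 1 seeds respectively), 16-trial null sessions × 10 seeds for
the chance-level guarantee (network families capped at 10 training epochs —
chance behaviour needs no convergence), 6 seeds for the 16-vs-64-trial
contrast with a separate 32-trial evaluation session, 1,000 random profiles
for the estimator-vs-oracle equivalence, 200 simulations × 300 bootstrap
replicates for CI calibration, and 5 replicate sessions in the acceptance
script. Larger runs change precision, not structure.

## Known limitations

* Synthetic rhythms are stationary band-limited noise; their ERD envelope
  is deterministic and identical across trials, unlike real single-trial
  variability.
* The EDF writer quantizes to 16 bits over the recording's amplitude range
  and pads the final 1 s record; events travel in a TSV sidecar rather than
  EDF+ annotations.
* No online/streaming detection loop, no bad-channel handling, no
  re-referencing schemes besides CAR, no time-frequency front-ends.
* CTD depends entirely on the host machine; only its arithmetic
  relationship to TTA is testable.
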