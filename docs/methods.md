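# Methods

## The superposition model

The frequency-following response (FFR) is a scalp potential phase-locked
to the periodicity of a voiced sound. The working hypothesis of this
package is linear superposition: the FFR is the convolution of a short
impulse response — the *F0 response* or kernel `k(τ)` — with the train of
F0-cycle events of the stimulus,

```
FFR(t) = Σ_j  a_j · k(t − t_j) + ε(t)
```

where `t_j` and `a_j` are the time and strength of the j-th F0 cycle.
Estimating `k` is a lagged regression: each pulse train is shifted in
steps of one sample (0.1 ms at the 10 kHz analysis rate) over the kernel
span, the shifted copies form the columns of a design matrix, and the
kernel is the ordinary-least-squares weight vector. Responses to all four
stimuli are explained by a *single* kernel; their design blocks are
concatenated with one lag span of invalid gap rows between them so no
stimulus bleeds into the next. The default span is 80 ms (800
regressors); the dual-bank nonlinear-linear model uses 45 ms for both the
F0-response and the stimulus-onset bank (2 × 450 = 900 regressors).

A stimulus set with a wide range of fundamental frequencies is essential:
for a constant-F0 stimulus, lags one period apart are nearly
interchangeable and the kernel is not meaningfully constrained. Because a
finite-length design is technically full rank (edges break periodicity),
the estimator flags this failure mode through three diagnostics: numerical
rank, condition number, and the maximum correlation between lag columns
(default threshold 0.95; the four-tone set measures ≈0.27, a constant-F0
train ≈0.96).

### Solver

The design is sparse (one entry per pulse per lag). The default solver
forms the normal equations from the sparse design and solves by Cholesky,
with a LAPACK reciprocal-condition estimate; a dense SVD solver
(`solver="direct"`) is available and both are tested against a dense
brute-force normal-equations oracle to 1e-10. The normal-equations route
exists because the adaptation fit evaluates the inner solve hundreds of
times; for the 13,200 × 900 session-level problem it runs in ~0.1 s. No
regularization is applied by default (the model is a plain linear model);
a ridge penalty is available for ill-conditioned user data.

## Polarity algebra

Stimuli are presented in condensation and rarefaction polarity. Averages
are combined as ENV = (condensation + rarefaction)/2 and TFS =
(condensation − rarefaction)/2, keeping per-trial microvolt units, so
ENV + TFS reconstructs the condensation average identically. The /2
convention (the sum-vs-difference choice leaves scale open) does not
affect variance-explained percentages, which are scale-invariant.

## Short-term adaptation stage

The purely linear model systematically misfits the first ~50 ms, where
the auditory periphery has not yet adapted to the repeated F0 cycles. The
nonlinear first stage is a standard single-resource short-term depression
model with two parameters: the per-event depletion fraction `U ∈ (0, 1]`
and the recovery time constant `τ` (ms). With resource `r_1 = 1`,

```
a'_k = a_k · r_k          (emitted amplitude)
r    ← r · (1 − U)        (post-event depletion)
r_{k+1} = 1 − (1 − r) · exp(−Δt_k / τ)   (recovery toward 1)
```

The depress-after-release convention (the k-th event is scaled by the
resource *before* its own depletion) is the standard form of this model
family; the recurrence is the exact solution of dr/dt = (1 − r)/τ between
events and is verified against fine-step numerical integration in the
tests.

`(U, τ)` are estimated by bounded quasi-Newton descent (L-BFGS-B on
`(U, log τ)`, bounds U ∈ [0.01, 0.99], τ ∈ [5, 500] ms, four fixed
multi-starts) on the training residual sum of squares; for every
candidate the kernels are profiled out by the exact inner least-squares
solve. The linear stage additionally carries the stimulus-onset bank (a
unit pulse at each stimulus's first event), allowing a qualitatively
distinct onset response.

Identifiability caveats, measured on synthetic data at full session
scale:

- On adaptation-free data, (small U, fast τ) acts as a pure amplitude
  rescaling that the profiled kernel absorbs: U sits on a flat likelihood
  ridge and its fitted value is arbitrary. The meaningful nested-model
  statements — the U→0 limit equals the linear fit, and the nonlinear
  model is no better than linear — hold and are tested.
- On adapted data (U = 0.4, τ = 60 ms) the likelihood valley around the
  optimum is a shallow ridge along which U and τ compensate each other.
  Across ten independent simulated sessions the recovered τ is stable
  (mean 65.5 ms, sd 7 ms — always within ±30% of truth) but U scatters
  widely (mean 0.47, sd 0.10, range 0.28–0.62, positive bias ≈ +0.07).
  Single-session estimates of τ are trustworthy; single-session estimates
  of U locate the right regime but not the precise value.

## Quantifying model fit

Percentage variance explained is baseline-corrected:

```
pve = 100 · (TMS − RMS) / (TMS − BMS)
```

with TMS the mean square of the data in the analysis window, RMS the mean
square of the residual, and BMS the mean square on the baseline — the
50 ms before stimulus onset and 320–390 ms after onset, both segments
weighted equally. The metric asks how much of the *explainable* variance
(the part exceeding the noise floor) the model captures, making sessions
with different signal-to-noise ratios comparable. Values may exceed 100
slightly (residual below the baseline floor) or be negative
(anti-prediction); both are reported as-is. Windows: full = 0–280 ms,
sustained = 50–250 ms, onset = 0–50 ms; the kernel is always fitted to
the entire duration, so window differences reflect where the same model
fits, not refitting.

Band-resolved variants apply the same formula to Morlet wavelet power
(complex Morlet, ~7 cycles; implemented as `cmor` with bandwidth
2·(7/2π)², center 1.0) integrated over the bands F0 = 70–170 Hz,
F1 = 180–300 Hz, Fx = 400–1200 Hz. All windows, including the baselines,
are shrunk by 20 ms on each side to absorb the wavelet's temporal
smearing.

Kernel similarity is the Pearson correlation of weight vectors on a
common lag grid.

### Overfitting controls

- split-half: trials of each condition are randomly halved; the kernel is
  fitted on one half's averages and evaluated on the other's.
- cross-session: each session is predicted only with kernels from other
  sessions; the session's metric is the mean over those kernels.
- shuffle: pulse trains are rotated by one stimulus (tone i gets tone
  i+1's train) and both fitting and prediction use the mismatched trains;
  with 800 free regressors this control verifies that fit quality comes
  from the stimulus-locked structure, not parameter count.

## Stimuli and F0-cycle events

Four 250 ms pitch contours with printed endpoints pinned exactly:
T1 level at 129 Hz; T2 rising 109→133 Hz (half cosine); T3 dipping from
111 Hz to a minimum of 89 Hz at 125 ms and back (full cosine; the
trajectory between the printed extrema is under-determined, the template
is a deliberate choice); T4 falling 140→92 Hz (half cosine). Tones are
rendered at 96 kHz as pulse-excited resonator cascades (default formants
280 and 2300 Hz, bandwidths 60/100 Hz, chosen so stimulus power falls in
the 180–300 Hz analysis band) plus a small parallel unfiltered excitation
path that keeps a sharp pressure landmark at each glottal instant.
Click-train versions place one 0.1 ms monophasic rectangular pulse per F0
cycle, timed and scaled by the detected cycle events; condensation is
positive-going, rarefaction is the exact negation.

Cycle boundaries come from the cumulative contour phase ∫f0 dt crossing
integers. Two event operationalizations:

- peak pressure: the argmax of pressure within the cycle (ties to the
  earliest sample); amplitude = 2 × |peak| to reflect the bidirectional
  modulation of speech-like waveforms.
- glottal pulse: the first positive local pressure maximum that lies
  within 1.5 ms of a local maximum of third-harmonic band power
  (zero-phase order-1 Butterworth at 3·f0 ± 30%, Hilbert envelope).
  Candidates below 10% of the cycle's peak pressure are discarded as
  ripple; cycles with no qualifying peak fall back to peak pressure, with
  a logged warning. The band, tolerance and ripple threshold are
  configurable; none are printed in the source literature.

On the resonator vowel the band-filter envelope smearing places the
third-harmonic power peak ~2 ms after the excitation, so glottal times
on those tones are accurate to a few tenths of a millisecond only. The
dedicated validation stimulus (`synth_glottal_pulse_stimulus`) emits
phase-aligned harmonics 3–8 at each excitation plus a slower
formant-like component whose pressure peak trails by ~1.5 ms; on it the
glottal estimate leads the peak-pressure estimate by ≈1.15 ms with
0.07 ms standard deviation and lands within ≈0.06 ms (median) of the true
excitation.

Amplitudes of the four click trains are normalized to a grand mean of 1
across the set before any fitting.

## Preprocessing

Second-order zero-phase Butterworth band-pass 60–2000 Hz; epoching on
[−50, 390] ms (covering both baseline segments); polyphase anti-aliased
decimation 30 kHz → 10 kHz with compensated group delay (an impulse at
the trigger lands in the t = 0 bin). Artifact rejection is relative per
channel: epochs whose peak-to-peak amplitude exceeds
median + 4 × IQR of that channel's distribution are masked for that
channel; epochs over threshold in ≥2 channels are masked everywhere. The
4×IQR cutoff is a package default (the criterion's distribution-based,
relative nature is fixed; its exact quantile is not). Session QC: the
mean squared baseline amplitude of the per-tone ENV averages must stay
strictly below 0.008 µV².

## The forward simulator

The generator exists to validate every stage end-to-end under known
ground truth. A session is 4 stimuli × 2 polarities × 500 trials (4,000
sweeps; the four bundled trains carry 116 events per sweep set, ~29 per
trial, ≈116,000 events per session). The ground-truth kernel is a sum of
Gabor atoms placed in the three latency/frequency regimes of the auditory
pathway: 4.5 ms at 600 Hz (brainstem-like, σ = 1.2 ms, 0.12 µV), 9 ms at
180 Hz (midbrain-like, σ = 2.5 ms, 0.20 µV), and 25 ms at 90 Hz
(cortex-like, σ = 5 ms, 0.14 µV). A distinct, larger stimulus-onset
response (18 ms, 110 Hz, 0.9 µV) is added at each stimulus's first event.
Optionally the pulse amplitudes pass through the adaptation stage, and a
polarity-antisymmetric mid-latency component (7 ms, 310 Hz) injects
fine-structure (TFS) content. Noise is per-trial band-limited (60–2000
Hz) 1/f pink noise at 1.5 µV RMS, independent across trials, behind one
seeded generator.

Amplitudes and noise were calibrated once so that a default session sits
in the regimes the source data report: averaged baseline noise
≈0.0023 µV² (well below the 0.008 µV² inclusion threshold) and
split-half/recovered-kernel correlations ≈0.97–0.98, the reported
cross-session reliability regime. With those defaults the simulated
phenomenology reproduces the qualitative fingerprints of the real data:
the 80 ms linear model explains ~97% of the sustained-window variance but
only ~30% of the onset window and ~64% of the full window; adding the
onset bank and adaptation lifts all three windows to ~100%; the shuffle
control collapses to ≈0%.

What the simulator does **not** emulate: volume conduction and realistic
channel topographies (only per-channel gain factors), non-stationary or
artifact-laden noise, trial-to-trial latency jitter, nonlinearities
beyond single-resource depression, and any biophysics of the individual
auditory nuclei. Passing tests therefore demonstrate the correctness and
statistical behavior of the estimation machinery under the model's own
assumptions, not the physiological accuracy of the model on real EEG.

## Problem sizes and determinism

All simulations in the tests and the acceptance script run at full
session scale (4,000 sweeps, ≈116,000 events); a complete
simulate → average → deconvolve → quantify cycle takes a few seconds.
Every random step draws from `numpy` generators seeded explicitly; the
acceptance script derives independent per-stage sub-seeds from its single
`--seed` argument, and identical seeds give bit-identical outputs.
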