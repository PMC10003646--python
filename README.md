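# ffrdeconv

Deconvolution of frequency-following responses (FFRs): recover the
per-F0-cycle impulse response of the auditory system from multi-trial
EEG, model short-term adaptation, and quantify fit with
baseline-corrected variance explained.

## The problem

The FFR is a scalp potential phase-locked to the periodicity of a voiced
sound — a workhorse measure in auditory neuroscience and in clinical
studies of pitch encoding. Because every F0 cycle of the stimulus evokes
a response that outlasts the cycle, the measured FFR is a dense
superposition of overlapping responses, and its shape conflates stimulus
periodicity with the system's own impulse response. Under the
superposition hypothesis,

```
FFR(t) = Σ_j a_j · k(t − t_j) + noise
```

the FFR elicited by a stimulus with F0-cycle events at times `t_j` and
strengths `a_j` is the convolution of a single short kernel `k` (the *F0
response*) with the event train. `ffrdeconv` estimates `k` by lagged
regression: the event train, shifted in 0.1 ms steps over an 80 ms span,
forms 800 regressors, and the kernel is the ordinary-least-squares weight
vector that jointly explains the responses to a set of stimuli with
time-varying pitch (the four Mandarin-tone F0 contours, 89–140 Hz, and
their click-train equivalents). Summing or differencing the responses to
opposite stimulus polarities isolates the envelope (FFR_ENV) or temporal
fine structure (FFR_TFS) component before deconvolution.

Two refinements complete the model: a stimulus-onset regressor bank (the
first F0 cycle may trigger a qualitatively distinct onset response) and a
nonlinear first stage of short-term adaptation, in which each event
depletes a fraction `U` of a resource that recovers with time constant
`τ` — two parameters fitted by bounded quasi-Newton descent with the
kernels profiled out by exact inner least squares.

Fit quality is reported as baseline-corrected percentage variance
explained, `100·(TMS − RMS)/(TMS − BMS)`, over the full (0–280 ms),
sustained (50–250 ms) and onset (0–50 ms) windows and over wavelet bands
(F0 70–170 Hz, F1 180–300 Hz, Fx 400–1200 Hz), with split-half,
cross-session and shuffled-train overfitting controls.

A forward simulator generates complete synthetic sessions (4 stimuli ×
2 polarities × 500 trials) from a known ground-truth kernel with
brainstem/midbrain/cortex-like components, optional adaptation and onset
responses, and band-limited pink noise — so every stage of the pipeline
is validated end-to-end against known truth.

## Worked example

```python
from ffrdeconv import (GroundTruthConfig, average_responses,
                       baseline_noise_qc, kernel_similarity,
                       simulate_session)
from ffrdeconv.pipeline import evaluate_fit, fit_linear, stimulus_pulse_trains

trains, stimuli, contours = stimulus_pulse_trains()
print("F0 cycles per stimulus:", {t.stimulus_id: len(t) for t in trains})

config = GroundTruthConfig(seed=42)   # 4 tones x 2 polarities x 500 trials
epochs, truth = simulate_session(config, trains)
avg = average_responses(epochs)
noise, ok = baseline_noise_qc(avg)
print(f"baseline noise: {noise:.4f} uV^2 (QC pass: {ok})")

model = fit_linear(avg, trains, lag_span_ms=45.0, include_onset=True)
print(f"recovered vs true kernel: r = "
      f"{kernel_similarity(model.kernel_, truth['kernel']):.3f}")

report = evaluate_fit(model, trains, avg)
for window in ("full", "sustained", "onset"):
    print(f"pve {window}: {report[window].pve:.1f}%")
```

prints

```
F0 cycles per stimulus: {'T1': 32, 'T2': 30, 'T3': 25, 'T4': 29}
baseline noise: 0.0024 uV^2 (QC pass: True)
recovered vs true kernel: r = 0.987
pve full: 100.9%
pve sustained: 101.1%
pve onset: 100.7%
```

The session passes the 0.008 µV² baseline-noise inclusion criterion, the
45 ms dual-bank model recovers the generating kernel almost perfectly,
and it explains essentially all explainable variance in every window
(values slightly above 100% arise when the residual drops below the
baseline noise floor). Refitting the same data with the plain 80 ms
linear model — no onset bank — reproduces the characteristic failure
mode that motivates the two-stage model: ~97% variance explained in the
sustained window but only ~30% around stimulus onset.

The same workflow is available from the shell:

```
ffrdeconv simulate --seed 42 --out session.h5
ffrdeconv deconvolve --epochs session.h5 --span 80 --out kernel.csv
ffrdeconv metrics --epochs session.h5 --kernel kernel.csv --out report.json
ffrdeconv fit-adapt --epochs session.h5 --out nl_fit.json
```

Each run writes a manifest (seed, config hash, versions) next to its
output; identical seeds give bit-identical results.

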