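"""Forward generative model for synthetic FFR sessions.

A ground-truth kernel is composed of Gabor atoms sitting in the three
latency/frequency regimes of the auditory pathway — fast high-frequency
components at short latencies (< 5 ms, 200-1000 Hz), mid-latency
components (5-15 ms, 100-250 Hz), and slow ~90 Hz components at 15-35 ms.
Each simulated trial is the superposition of kernel copies at the
(optionally adapted) F0-cycle events, plus an optional distinct
stimulus-onset response, an optional polarity-antisymmetric fine-structure
component, and additive band-limited 1/f^alpha noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adaptation import AdaptationParams, apply_adaptation
from .deconv import DEFAULT_RATE, predict_waveform
from .events import PulseTrain
from .preprocess import CONDENSATION, EPOCH_WINDOW_MS, RAREFACTION, EpochSet


@dataclass(frozen=True)
class GaborAtom:
    """One kernel component: a Gaussian-windowed cosine.

    latency_ms is the envelope center, sd_ms its standard deviation,
    amp_uv the peak amplitude in microvolts.
    """

    latency_ms: float
    freq_hz: float
    sd_ms: float
    amp_uv: float
    phase_rad: float = 0.0

    def sample(self, lags_ms: np.ndarray) -> np.ndarray:
        dt = lags_ms - self.latency_ms
        return (self.amp_uv * np.exp(-0.5 * (dt / self.sd_ms) ** 2)
                * np.cos(2.0 * np.pi * self.freq_hz * dt / 1000.0
                         + self.phase_rad))


#: default kernel components, one per latency/frequency regime
DEFAULT_COMPONENTS = (
    GaborAtom(latency_ms=4.5, freq_hz=600.0, sd_ms=1.2, amp_uv=0.12),
    GaborAtom(latency_ms=9.0, freq_hz=180.0, sd_ms=2.5, amp_uv=0.20),
    GaborAtom(latency_ms=25.0, freq_hz=90.0, sd_ms=5.0, amp_uv=0.14),
)

#: default stimulus-onset response, larger and slower than the F0 kernel
DEFAULT_ONSET_COMPONENTS = (
    GaborAtom(latency_ms=18.0, freq_hz=110.0, sd_ms=6.0, amp_uv=0.9),
)

#: optional fine-structure component at mid latency; its response flips
#: sign with stimulus polarity
DEFAULT_TFS_COMPONENTS = (
    GaborAtom(latency_ms=7.0, freq_hz=310.0, sd_ms=2.0, amp_uv=0.05),
)


@dataclass
class GroundTruthConfig:
    """Everything the forward model needs to synthesize one session.

    Defaults emulate one recording session: 4 stimuli x 2 polarities x
    500 trials (4,000 sweeps), per-trial band-limited pink noise whose
    500-trial averages land well below the 0.008 microvolt^2 baseline QC
    threshold, and a 45 ms ground-truth kernel so both the 80 ms linear
    model and the 45 ms nonlinear-linear model contain it.
    """

    components: tuple = DEFAULT_COMPONENTS
    onset_components: tuple = DEFAULT_ONSET_COMPONENTS
    tfs_components: tuple = ()
    adaptation: AdaptationParams | None = None
    lag_span_ms: float = 45.0
    noise_alpha: float = 1.0
    noise_rms_uv: float = 1.5
    noise_band_hz: tuple = (60.0, 2000.0)
    n_trials: int = 500
    n_channels: int = 1
    channel_gains: np.ndarray | None = None
    rate: float = DEFAULT_RATE
    epoch_window_ms: tuple = EPOCH_WINDOW_MS
    seed: int = 0


def make_ground_truth_kernel(components, lag_span_ms: float = 45.0,
                             rate: float = DEFAULT_RATE) -> np.ndarray:
    """Sample the sum of Gabor atoms on the lag grid (0.1 ms steps)."""
    n_lags = int(round(lag_span_ms * rate / 1000.0))
    lags = np.arange(n_lags) / rate * 1000.0
    for atom in components:
        if not (0.0 <= atom.latency_ms <= lag_span_ms):
            raise ValueError(f"atom at {atom.latency_ms} ms outside the "
                             f"{lag_span_ms} ms lag span")
    k = np.zeros(n_lags)
    for atom in components:
        k += atom.sample(lags)
    return k


def colored_noise(shape, rate: float, rng: np.random.Generator,
                  alpha: float = 1.0, band_hz=(60.0, 2000.0),
                  rms: float = 1.0) -> np.ndarray:
    """Band-limited 1/f^alpha Gaussian noise, scaled to a target RMS.

    ``rms = 0`` yields silence (the noise-free validation case).
    """
    if rms < 0:
        raise ValueError("noise level must be nonnegative")
    if rms == 0:
        return np.zeros(shape)
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    gain = np.zeros_like(freqs)
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    gain[sel] = freqs[sel] ** (-alpha / 2.0)
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * gain
    x = np.fft.irfft(spec, n=n, axis=-1)
    x *= rms / np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x


def simulate_session(config: GroundTruthConfig,
                     trains: list[PulseTrain]) -> tuple[EpochSet, dict]:
    """Synthesize one multi-trial session from the ground-truth model.

    Returns the epochs (trials x channels x time on the epoch clock) and a
    ground-truth record with the kernels and parameters that generated
    them.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.rate
    t0, t1 = config.epoch_window_ms
    n_t = int(round((t1 - t0) / 1000.0 * rate))
    onset_shift = int(round(-t0 / 1000.0 * rate))
    kernel = make_ground_truth_kernel(config.components, config.lag_span_ms, rate)
    onset_kernel = (make_ground_truth_kernel(config.onset_components,
                                             config.lag_span_ms, rate)
                    if config.onset_components else None)
    tfs_kernel = (make_ground_truth_kernel(config.tfs_components,
                                           config.lag_span_ms, rate)
                  if config.tfs_components else None)
    gains = (np.ones(config.n_channels) if config.channel_gains is None
             else np.asarray(config.channel_gains, dtype=float))
    if len(gains) != config.n_channels:
        raise ValueError("channel_gains must have n_channels entries")

    data, sids, pols = [], [], []
    for train in trains:
        adapted = (apply_adaptation(train, config.adaptation)
                   if config.adaptation else train)
        shifted = PulseTrain(stimulus_id=train.stimulus_id,
                             onsets_ms=adapted.onsets_ms - t0,
                             amplitudes=adapted.amplitudes,
                             method=adapted.method)
        base = predict_waveform(kernel, shifted, n_t, rate)[0]
        if onset_kernel is not None:
            s = int(round(shifted.onsets_ms[0] / 1000.0 * rate))
            hi = min(s + len(onset_kernel), n_t)
            base = base.copy()
            base[s:hi] += onset_kernel[:hi - s]
        tfs = (predict_waveform(tfs_kernel, shifted, n_t, rate)[0]
               if tfs_kernel is not None else 0.0)
        for pol, sign in ((CONDENSATION, 1.0), (RAREFACTION, -1.0)):
            signal = base + sign * tfs
            noise = colored_noise((config.n_trials, config.n_channels, n_t),
                                  rate, rng, alpha=config.noise_alpha,
                                  band_hz=config.noise_band_hz,
                                  rms=config.noise_rms_uv)
            trials = noise + signal[None, None, :] * gains[None, :, None]
            data.append(trials)
            sids.extend([train.stimulus_id] * config.n_trials)
            pols.extend([pol] * config.n_trials)
    epochs = EpochSet(data=np.concatenate(data, axis=0), rate=rate,
                      t_start_ms=t0, stimulus_ids=np.array(sids),
                      polarities=np.array(pols))
    ground_truth = {"kernel": kernel, "onset_kernel": onset_kernel,
                    "tfs_kernel": tfs_kernel, "adaptation": config.adaptation,
                    "lags_ms": np.arange(len(kernel)) / rate * 1000.0,
                    "seed": config.seed}
    return epochs, ground_truth
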