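"""EEG preprocessing: filtering, epoching, artifact rejection, averaging, QC.

The pipeline mirrors standard frequency-following-response practice:
zero-phase band-pass (60-2000 Hz), epoching around stimulus onset,
downsampling to the 10 kHz analysis rate, a relative peak-to-peak artifact
criterion per channel, per-condition averaging, and the polarity algebra
that separates envelope (ENV = sum/2) from temporal fine structure
(TFS = difference/2) responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .stimuli import CONDENSATION, RAREFACTION

ANALYSIS_RATE = 10000.0
EPOCH_WINDOW_MS = (-50.0, 390.0)
BASELINE_WINDOWS_MS = ((-50.0, 0.0), (320.0, 390.0))
QC_THRESHOLD_UV2 = 0.008

ENV = "ENV"
TFS = "TFS"


@dataclass
class EpochSet:
    """Multi-trial epoched EEG with per-trial condition labels.

    ``data`` is trials x channels x time in microvolts; ``t_start_ms`` is
    the epoch clock of the first sample relative to stimulus onset;
    ``rejected`` is a trials x channels boolean mask (True = excluded).
    """

    data: np.ndarray
    rate: float
    t_start_ms: float
    stimulus_ids: np.ndarray
    polarities: np.ndarray
    rejected: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.atleast_3d(np.asarray(self.data, dtype=float))
        n_trials = self.data.shape[0]
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        self.polarities = np.asarray(self.polarities)
        if len(self.stimulus_ids) != n_trials or len(self.polarities) != n_trials:
            raise ValueError("labels must cover every trial")
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[:2], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.data.shape[2]) / self.rate * 1000.0


@dataclass
class AverageResponse:
    """Per-condition average waveforms (channels x time, microvolts).

    ``waves`` is keyed by ``(stimulus_id, component)`` where component is
    one of ``condensation``, ``rarefaction``, ``ENV``, ``TFS``; ``n_trials``
    records the trial count behind each polarity average.
    """

    waves: dict
    rate: float
    t_start_ms: float
    n_trials: dict

    @property
    def stimulus_ids(self) -> list:
        return sorted({k[0] for k in self.waves})

    @property
    def times_ms(self) -> np.ndarray:
        n = len(next(iter(self.waves.values()))[0])
        return self.t_start_ms + np.arange(n) / self.rate * 1000.0

    def get(self, stimulus_id, component=ENV) -> np.ndarray:
        return self.waves[(stimulus_id, component)]


def bandpass_zero_phase(raw: np.ndarray, low: float = 60.0, high: float = 2000.0,
                        rate: float = 30000.0, order: int = 2) -> np.ndarray:
    """Forward-backward Butterworth band-pass along the last axis."""
    if high >= rate / 2:
        raise ValueError("upper cutoff at or above Nyquist")
    sos = butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sosfiltfilt(sos, raw, axis=-1)


def epoch_downsample(raw: np.ndarray, rate: float, trigger_samples: np.ndarray,
                     window_ms: tuple = EPOCH_WINDOW_MS,
                     target_rate: float = ANALYSIS_RATE) -> np.ndarray:
    """Cut time-locked epochs and decimate to the analysis rate.

    ``raw`` is channels x samples; triggers are sample indices of stimulus
    onset at the raw rate.  Decimation uses a polyphase anti-aliasing FIR
    whose group delay is compensated, so an impulse at the trigger lands in
    the epoch's t = 0 bin.  Returns trials x channels x time.
    """
    raw = np.atleast_2d(raw)
    q, rem = divmod(rate, target_rate)
    if rem:
        raise ValueError("target rate must divide the raw rate")
    q = int(q)
    n0 = int(round(window_ms[0] / 1000.0 * rate))
    n1 = int(round(window_ms[1] / 1000.0 * rate))
    trigger_samples = np.asarray(trigger_samples, dtype=int)
    epochs = []
    for trig in trigger_samples:
        a, b = trig + n0, trig + n1
        if a < 0 or b > raw.shape[1]:
            raise ValueError(f"epoch at trigger {trig} exceeds recording bounds")
        seg = raw[:, a:b]
        epochs.append(resample_poly(seg, 1, q, axis=-1) if q > 1 else seg)
    if not epochs:
        n_out = (n1 - n0) // q
        return np.empty((0, raw.shape[0], n_out))
    return np.stack(epochs)


def reject_artifacts(epochs: EpochSet, n_iqr: float = 4.0,
                     cross_channel_min: int = 2) -> EpochSet:
    """Mask epochs whose peak-to-peak amplitude is an outlier per channel.

    The criterion is relative to each channel's own distribution
    (threshold = median + ``n_iqr`` * IQR of the peak-to-peak amplitudes),
    so channels with different noise floors share one rule.  An epoch over
    threshold in >= ``cross_channel_min`` channels is rejected for all
    channels.  Data are untouched; only the mask is updated.
    """
    if epochs.n_trials < 10:
        raise ValueError("need >=10 epochs to estimate the amplitude distribution")
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    med = np.median(p2p, axis=0)
    q75, q25 = np.percentile(p2p, [75, 25], axis=0)
    thresh = med + n_iqr * (q75 - q25)
    over = p2p > thresh
    mask = over.copy()
    mask[over.sum(axis=1) >= cross_channel_min, :] = True
    frac = mask.mean(axis=0)
    if np.any(frac > 0.9):
        raise ValueError("artifact criterion would reject >90% of epochs; "
                         "check the configuration")
    out = EpochSet(data=epochs.data, rate=epochs.rate,
                   t_start_ms=epochs.t_start_ms,
                   stimulus_ids=epochs.stimulus_ids,
                   polarities=epochs.polarities,
                   rejected=epochs.rejected | mask)
    return out


def average_responses(epochs: EpochSet) -> AverageResponse:
    """Average valid trials per (stimulus, polarity) and derive ENV/TFS.

    ENV = (condensation + rarefaction) / 2 and
    TFS = (condensation - rarefaction) / 2, keeping per-trial microvolt
    units; their sum reconstructs the condensation average identically.
    """
    waves, counts = {}, {}
    for sid in np.unique(epochs.stimulus_ids):
        for pol in (CONDENSATION, RAREFACTION):
            sel = (epochs.stimulus_ids == sid) & (epochs.polarities == pol)
            if not np.any(sel):
                raise ValueError(f"no trials for ({sid}, {pol})")
            d = epochs.data[sel]            # trials x ch x time
            valid = ~epochs.rejected[sel]   # trials x ch
            n_valid = valid.sum(axis=0)     # per channel
            if np.any(n_valid == 0):
                raise ValueError(f"all trials rejected for ({sid}, {pol}) "
                                 "in at least one channel")
            avg = np.einsum("tcx,tc->cx", d, valid.astype(float))
            avg /= n_valid[:, None]
            waves[(sid, pol)] = avg
            counts[(sid, pol)] = n_valid
        c, r = waves[(sid, CONDENSATION)], waves[(sid, RAREFACTION)]
        waves[(sid, ENV)] = (c + r) / 2.0
        waves[(sid, TFS)] = (c - r) / 2.0
    return AverageResponse(waves=waves, rate=epochs.rate,
                           t_start_ms=epochs.t_start_ms, n_trials=counts)


def baseline_noise_qc(avg: AverageResponse,
                      threshold_uv2: float = QC_THRESHOLD_UV2,
                      baselines_ms: tuple = BASELINE_WINDOWS_MS,
                      component: str = ENV) -> tuple[float, bool]:
    """Session data-quality check on residual baseline noise.

    Returns the mean squared baseline amplitude (microvolt^2) of the
    per-tone averages — both baseline segments weighted equally, averaged
    over tones and channels — and whether it is strictly below the
    inclusion threshold.
    """
    t = avg.times_ms
    seg_ms = []
    for lo, hi in baselines_ms:
        sel = (t >= lo) & (t < hi)
        if not np.any(sel):
            raise ValueError(f"baseline window [{lo}, {hi}) ms not in epoch")
        seg_ms.append(np.mean(
            [np.mean(avg.get(sid, component)[:, sel] ** 2)
             for sid in avg.stimulus_ids]))
    noise = float(np.mean(seg_ms))
    return noise, noise < threshold_uv2
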