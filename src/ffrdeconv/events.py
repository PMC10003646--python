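"""F0-cycle event detection and pulse-train bookkeeping.

Every F0 cycle of a voiced stimulus is summarized by a single timestamped
Dirac event whose amplitude reflects the cycle's intensity.  Two
operationalizations are provided: the time of the peak pressure within the
cycle, and the glottal-pulse time — the first positive pressure peak that
coincides with a peak of power in the third harmonic of F0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .stimuli import AudioStimulus, F0Contour

logger = logging.getLogger(__name__)

PEAK_PRESSURE = "peak_pressure"
GLOTTAL_PULSE = "glottal_pulse"
EXPLICIT = "explicit"


@dataclass(frozen=True)
class PulseTrain:
    """Timestamped Dirac events representing a stimulus, one per F0 cycle."""

    stimulus_id: str
    onsets_ms: np.ndarray
    amplitudes: np.ndarray
    method: str = EXPLICIT

    def __post_init__(self):
        onsets = np.asarray(self.onsets_ms, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if onsets.shape != amps.shape or onsets.ndim != 1:
            raise ValueError("onsets and amplitudes must be 1-D and equal length")
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be nonnegative")
        object.__setattr__(self, "onsets_ms", onsets)
        object.__setattr__(self, "amplitudes", amps)

    def __len__(self) -> int:
        return len(self.onsets_ms)

    def scaled(self, factor: float) -> "PulseTrain":
        return replace(self, amplitudes=self.amplitudes * factor)


def _cycle_windows(contour: F0Contour, n_samples: int, rate: float):
    """Per-cycle (start, stop) sample index pairs from the contour phase."""
    bounds = contour.cycle_boundaries_ms()
    idx = np.round(bounds / 1000.0 * rate).astype(int)
    idx = np.clip(idx, 0, n_samples)
    return [(idx[k], idx[k + 1]) for k in range(len(idx) - 1) if idx[k + 1] > idx[k]]


def detect_cycle_events_peak(stimulus: AudioStimulus,
                             contour: F0Contour) -> PulseTrain:
    """One event per F0 cycle at the time of peak pressure.

    The event amplitude is twice the absolute peak pressure, accounting for
    the bidirectional modulation of speech-like pressure waveforms.  Ties
    in the argmax break to the earliest sample.
    """
    w = stimulus.samples
    if contour.duration_ms < stimulus.duration_ms - 1e-6:
        raise ValueError("contour does not cover the waveform duration")
    onsets, amps = [], []
    for a, b in _cycle_windows(contour, len(w), stimulus.rate):
        seg = w[a:b]
        if not np.any(seg):
            raise ValueError(f"all-zero F0 cycle in [{a}, {b}) samples")
        peak = a + int(np.argmax(seg))
        onsets.append(peak / stimulus.rate * 1000.0)
        amps.append(2.0 * abs(w[peak]))
    return PulseTrain(stimulus_id=stimulus.tone_id or "stim",
                      onsets_ms=np.asarray(onsets), amplitudes=np.asarray(amps),
                      method=PEAK_PRESSURE)


def _third_harmonic_power(w: np.ndarray, rate: float, fc: float,
                          rel_band: float = 0.3) -> np.ndarray:
    """Hilbert-envelope power of the band around the third harmonic.

    A first-order zero-phase Butterworth keeps the band edges soft and the
    temporal smearing of the envelope small, so the power peak stays close
    to the excitation burst it reflects.
    """
    lo = max(fc * (1.0 - rel_band), 1.0)
    hi = min(fc * (1.0 + rel_band), rate / 2 * 0.99)
    sos = butter(1, [lo, hi], btype="bandpass", fs=rate, output="sos")
    band = sosfiltfilt(sos, w)
    return np.abs(hilbert(band)) ** 2


def detect_cycle_events_glottal(stimulus: AudioStimulus, contour: F0Contour,
                                coincidence_tol_ms: float = 1.5,
                                rel_band: float = 0.3,
                                min_rel_amp: float = 0.1) -> PulseTrain:
    """One event per F0 cycle at the estimated glottal-pulse time.

    The glottal pulse is operationalized as the first positive local
    pressure maximum within the cycle whose time lies within
    ``coincidence_tol_ms`` of a local maximum of power in the third
    harmonic (a band at 3*f0 +- ``rel_band``).  Candidate peaks smaller
    than ``min_rel_amp`` of the cycle's peak pressure are ignored as
    ripple; cycles with no qualifying peak fall back to the peak-pressure
    time (logged).  The amplitude rule
    is identical to the peak-pressure method: twice the absolute peak
    pressure of the cycle.
    """
    w = stimulus.samples
    rate = stimulus.rate
    if contour.duration_ms < stimulus.duration_ms - 1e-6:
        raise ValueError("contour does not cover the waveform duration")
    windows = _cycle_windows(contour, len(w), rate)
    mids = [(a + b) / 2 / rate * 1000.0 for a, b in windows]
    onsets, amps = [], []
    n_fallback = 0
    for (a, b), mid in zip(windows, mids):
        f0 = float(contour.f0_at(mid))
        if 3.0 * f0 >= rate / 2:
            raise ValueError("third harmonic above Nyquist")
        power = _third_harmonic_power(w, rate, 3.0 * f0, rel_band)
        seg = w[a:b]
        pk = a + int(np.argmax(seg))
        amp = 2.0 * abs(w[pk])
        # local maxima of band power, searched slightly beyond the cycle edge
        lo, hi = a, min(b + 1, len(w) - 1)
        p = power[lo:hi + 1]
        pmax = lo + 1 + np.flatnonzero((p[1:-1] >= p[:-2]) & (p[1:-1] > p[2:]))
        # positive local pressure maxima within the cycle; the window opens
        # one sample early so a peak on the boundary sample is interior
        a0 = max(a - 1, 0)
        s = w[a0:min(b + 1, len(w))]
        cand = a0 + 1 + np.flatnonzero(
            (s[1:-1] >= s[:-2]) & (s[1:-1] > s[2:])
            & (s[1:-1] > min_rel_amp * abs(w[pk])))
        cand = cand[cand >= a]
        tol = coincidence_tol_ms / 1000.0 * rate
        chosen = None
        for c in cand:
            if pmax.size and np.min(np.abs(pmax - c)) <= tol:
                chosen = c
                break
        if chosen is None:
            n_fallback += 1
            chosen = pk
        onsets.append(chosen / rate * 1000.0)
        amps.append(amp)
    if n_fallback:
        logger.warning("glottal detection fell back to peak pressure for "
                       "%d/%d cycles", n_fallback, len(windows))
    return PulseTrain(stimulus_id=stimulus.tone_id or "stim",
                      onsets_ms=np.asarray(onsets), amplitudes=np.asarray(amps),
                      method=GLOTTAL_PULSE)


def normalize_amplitudes(trains: list[PulseTrain]) -> list[PulseTrain]:
    """Scale all trains so the grand-mean event amplitude across the set is 1."""
    if not trains or not any(len(t) for t in trains):
        raise ValueError("need at least one train with at least one event")
    grand = np.concatenate([t.amplitudes for t in trains if len(t)])
    m = float(np.mean(grand))
    if m == 0:
        raise ValueError("all amplitudes are zero; cannot normalize")
    return [t.scaled(1.0 / m) for t in trains]


def shuffle_rotate(trains: list[PulseTrain]) -> list[PulseTrain]:
    """Cyclic shuffle control: stimulus i is assigned the train of stimulus i+1.

    The rotated events keep their timing and amplitudes but inherit the
    stimulus id of the position they now predict, so downstream code pairs
    them with the wrong (mismatched) responses by construction.
    """
    if len(trains) != 4:
        raise ValueError("shuffle rotation is defined for exactly 4 trains")
    rotated = trains[1:] + trains[:1]
    return [replace(src, stimulus_id=dst.stimulus_id)
            for dst, src in zip(trains, rotated)]
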