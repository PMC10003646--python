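"""Stimulus synthesis: F0 contours, vowel-like harmonic tones, and click trains.

Four pitch contours (T1-T4, the classic level / rising / dipping / falling
patterns of Mandarin lexical tones) are imposed on a vowel-like carrier.
Each stimulus is also rendered as a click train whose clicks match the
timing and amplitude of the F0 cycles, and every stimulus exists in both
presentation polarities (condensation = positive-going, rarefaction = its
negation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

TONE_IDS = ("T1", "T2", "T3", "T4")

#: printed F0 endpoints/extrema in Hz per tone: (start, end, extremum or None)
_F0_RANGES = {
    "T1": (129.0, 129.0, None),
    "T2": (109.0, 133.0, None),
    "T3": (111.0, 111.0, 89.0),  # full-cosine dip, minimum mid-stimulus
    "T4": (140.0, 92.0, None),
}

DEFAULT_DURATION_MS = 250.0
DEFAULT_AUDIO_RATE = 96000.0
CLICK_WIDTH_MS = 0.1

CONDENSATION = "condensation"
RAREFACTION = "rarefaction"


@dataclass(frozen=True)
class F0Contour:
    """Instantaneous fundamental-frequency trajectory of one stimulus.

    Attributes
    ----------
    tone_id : str
        One of ``T1``-``T4``.
    t_ms : ndarray
        Time grid in ms over ``[0, duration]``.
    f0_hz : ndarray
        Instantaneous fundamental in Hz on ``t_ms``.
    """

    tone_id: str
    t_ms: np.ndarray
    f0_hz: np.ndarray

    def __post_init__(self):
        if len(self.t_ms) != len(self.f0_hz):
            raise ValueError("t_ms and f0_hz must have equal length")
        if len(self.t_ms) < 2:
            raise ValueError("contour needs at least two samples")

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1])

    def f0_at(self, t_ms) -> np.ndarray:
        """Interpolate f0 (Hz) at arbitrary times (ms)."""
        return np.interp(t_ms, self.t_ms, self.f0_hz)

    def phase_cycles(self) -> np.ndarray:
        """Cumulative phase in cycles, phi(t) = integral of f0 dt, phi(0)=0."""
        return cumulative_trapezoid(self.f0_hz, self.t_ms / 1000.0, initial=0.0)

    def cycle_boundaries_ms(self) -> np.ndarray:
        """Times at which the cumulative phase crosses integers 0, 1, 2, ...

        Returns K+1 boundaries for K complete F0 cycles
        (K = floor(total phase)); cycle k spans
        ``[boundaries[k], boundaries[k+1])``.
        """
        phi = self.phase_cycles()
        # guard against an exact integer total landing just below it in float
        n_complete = int(np.floor(phi[-1] + 1e-9))
        ks = np.arange(n_complete + 1)
        return np.interp(ks, phi, self.t_ms)

    @property
    def n_cycles(self) -> int:
        """Number of complete F0 cycles within the stimulus duration."""
        return len(self.cycle_boundaries_ms()) - 1


def make_f0_contour(tone_id: str, duration_ms: float = DEFAULT_DURATION_MS,
                    dt_ms: float = 0.1, template: str = "raised_cosine") -> F0Contour:
    """Build the F0 contour for one of the four tones.

    The printed endpoints/extrema are pinned exactly; the trajectory in
    between follows a raised-cosine template (T1 flat, T2/T4 half-cosine
    monotone, T3 full-cosine dip with its minimum at mid-stimulus).
    """
    if tone_id not in _F0_RANGES:
        raise ValueError(f"unknown tone_id {tone_id!r}; expected one of {TONE_IDS}")
    if template != "raised_cosine":
        raise ValueError(f"unknown contour template {template!r}")
    start, end, extremum = _F0_RANGES[tone_id]
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    x = t / duration_ms
    if extremum is not None:
        # symmetric dip: start -> extremum at mid-stimulus -> end
        f0 = extremum + (start - extremum) * 0.5 * (1.0 + np.cos(2.0 * np.pi * x))
    else:
        # monotone half cosine from start to end (flat when start == end)
        f0 = end + (start - end) * 0.5 * (1.0 + np.cos(np.pi * x))
    return F0Contour(tone_id=tone_id, t_ms=t, f0_hz=f0)


@dataclass(frozen=True)
class FormantConfig:
    """Resonator cascade for the vowel-like carrier.

    Defaults place the first formant at 280 Hz so that stimulus power falls
    in the 180-300 Hz analysis band, with a high second formant typical of
    a close front vowel.
    """

    freqs_hz: tuple = (280.0, 2300.0)
    bandwidths_hz: tuple = (60.0, 100.0)
    #: gain of the parallel (unfiltered) excitation path; keeps a sharp
    #: pressure peak at each glottal instant without dominating the cycle
    direct_gain: float = 0.15

    def __post_init__(self):
        if len(self.freqs_hz) < 2 or len(self.freqs_hz) != len(self.bandwidths_hz):
            raise ValueError("need >=2 formants with matching bandwidths")


@dataclass(frozen=True)
class AudioStimulus:
    """A rendered pressure waveform (arbitrary units, peak-normalized).

    ``excitation_ms`` carries the ground-truth excitation instants used
    during synthesis (one per complete F0 cycle); it is metadata for
    validation and is not used by any analysis path.
    """

    samples: np.ndarray
    rate: float
    polarity: str
    kind: str  # "tone" | "click_train"
    tone_id: str | None = None
    excitation_ms: np.ndarray | None = field(default=None, repr=False)

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.rate * 1000.0

    def flipped(self) -> "AudioStimulus":
        """Opposite-polarity version (samples negated)."""
        other = RAREFACTION if self.polarity == CONDENSATION else CONDENSATION
        return replace(self, samples=-self.samples, polarity=other)


def _resonator_sos(freq_hz: float, bw_hz: float, rate: float) -> np.ndarray:
    """Second-order all-pole digital resonator section, unit gain at DC-free peak."""
    r = np.exp(-np.pi * bw_hz / rate)
    theta = 2.0 * np.pi * freq_hz / rate
    # normalize so the resonance gain is ~1
    g = (1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2.0 * theta) + r * r)
    return np.array([g, 0.0, 0.0, 1.0, -2.0 * r * np.cos(theta), r * r])


def synth_tone(contour: F0Contour, formants: FormantConfig | None = None,
               rate: float = DEFAULT_AUDIO_RATE,
               polarity: str = CONDENSATION) -> AudioStimulus:
    """Render a pitch-synchronous pulse-excited vowel-like stimulus.

    Excitation impulses are placed where the cumulative contour phase
    crosses integers (one per F0 cycle) and filtered through the formant
    resonator cascade; the result is peak-normalized to 1.
    """
    from scipy.signal import sosfilt

    if formants is None:
        formants = FormantConfig()
    if contour.duration_ms <= 0:
        raise ValueError("contour has zero duration")
    if max(formants.freqs_hz) >= rate / 2:
        raise ValueError("formant frequency above Nyquist for this sample rate")
    n = int(round(contour.duration_ms / 1000.0 * rate))
    boundaries = contour.cycle_boundaries_ms()
    excitation = boundaries[:-1]  # one excitation per complete cycle
    x = np.zeros(n)
    idx = np.round(excitation / 1000.0 * rate).astype(int)
    if np.any(idx >= n):
        raise ValueError("f0 grid incompatible with sample rate")
    x[idx] = 1.0
    y = x
    for f, bw in zip(formants.freqs_hz, formants.bandwidths_hz):
        y = sosfilt(_resonator_sos(f, bw, rate)[None, :], y)
    y = y + formants.direct_gain * np.max(np.abs(y)) * x
    y = y / np.max(np.abs(y))
    if polarity == RAREFACTION:
        y = -y
    elif polarity != CONDENSATION:
        raise ValueError(f"unknown polarity {polarity!r}")
    return AudioStimulus(samples=y, rate=rate, polarity=polarity, kind="tone",
                         tone_id=contour.tone_id, excitation_ms=excitation)


def synth_glottal_pulse_stimulus(contour: F0Contour,
                                 rate: float = DEFAULT_AUDIO_RATE,
                                 fast_decay_ms: float = 1.0,
                                 slow_freq_hz: float = 170.0,
                                 slow_decay_ms: float = 3.0,
                                 fast_gain: float = 0.08,
                                 polarity: str = CONDENSATION) -> AudioStimulus:
    """Synthetic glottal-pulse stimulus with controlled timing structure.

    Each excitation instant emits (a) a fast wideband burst of harmonics
    3-8 of the local F0, phase-aligned so the pressure and third-harmonic
    power both peak at the excitation itself, and (b) a slower
    formant-like component whose pressure peak lags by a quarter period of
    ``slow_freq_hz`` (~0.9 ms).  The cycle's peak pressure therefore
    trails the glottal instant, as in natural voiced speech, while the
    excitation times remain exactly known — the reference stimulus for
    validating glottal-pulse detection.
    """
    if contour.duration_ms <= 0:
        raise ValueError("contour has zero duration")
    n = int(round(contour.duration_ms / 1000.0 * rate))
    t = np.arange(n) / rate * 1000.0  # ms
    excitation = contour.cycle_boundaries_ms()[:-1]
    y = np.zeros(n)
    for t0 in excitation:
        f0 = float(np.interp(t0, contour.t_ms, contour.f0_hz))
        dt = t - t0
        m = (dt >= 0) & (dt < 5.0 / f0 * 1000.0)
        d = dt[m] / 1000.0  # s
        fast = np.zeros_like(d)
        for h in range(3, 9):
            fast += np.cos(2.0 * np.pi * h * f0 * d)
        fast *= np.exp(-dt[m] / fast_decay_ms) * fast_gain
        slow = np.exp(-dt[m] / slow_decay_ms) * np.sin(
            2.0 * np.pi * slow_freq_hz * d)
        y[m] += fast + slow
    y = y / np.max(np.abs(y))
    if polarity == RAREFACTION:
        y = -y
    elif polarity != CONDENSATION:
        raise ValueError(f"unknown polarity {polarity!r}")
    return AudioStimulus(samples=y, rate=rate, polarity=polarity, kind="tone",
                         tone_id=contour.tone_id, excitation_ms=excitation)


def synth_click_train(onsets_ms: np.ndarray, amplitudes: np.ndarray,
                      rate: float = DEFAULT_AUDIO_RATE,
                      duration_ms: float = DEFAULT_DURATION_MS,
                      polarity: str = CONDENSATION,
                      tone_id: str | None = None) -> AudioStimulus:
    """Render a train of 0.1 ms monophasic rectangular clicks.

    One click per event, scaled by the event amplitude; condensation
    clicks are positive-going.
    """
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if onsets_ms.size and (onsets_ms.min() < 0 or onsets_ms.max() > duration_ms):
        raise ValueError("pulse events outside [0, duration]")
    if onsets_ms.size > 1 and np.min(np.diff(np.sort(onsets_ms))) < CLICK_WIDTH_MS:
        raise ValueError("events closer than the 0.1 ms click width overlap")
    n = int(round(duration_ms / 1000.0 * rate))
    width = max(1, int(round(CLICK_WIDTH_MS / 1000.0 * rate)))
    y = np.zeros(n)
    for t, a in zip(onsets_ms, amplitudes):
        i = int(round(t / 1000.0 * rate))
        y[i:i + width] = a
    if polarity == RAREFACTION:
        y = -y
    elif polarity != CONDENSATION:
        raise ValueError(f"unknown polarity {polarity!r}")
    return AudioStimulus(samples=y, rate=rate, polarity=polarity,
                         kind="click_train", tone_id=tone_id,
                         excitation_ms=onsets_ms.copy())
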