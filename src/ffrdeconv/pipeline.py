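"""End-to-end convenience layer: stimuli to fitted models and fit reports.

These helpers wire the modules together the way a full analysis runs:
synthesize the four tone stimuli, derive normalized F0-cycle pulse
trains, simulate or load a session, average into ENV/TFS responses, fit
the linear (and optionally nonlinear-linear) model, and report
baseline-corrected variance explained over windows and bands.
"""

from __future__ import annotations

import numpy as np

from . import events as ev
from . import metrics
from .adaptation import AdaptiveDeconvolver
from .deconv import KernelDeconvolver, _responses_for
from .preprocess import ENV, AverageResponse
from .stimuli import TONE_IDS, make_f0_contour, synth_tone


def stimulus_pulse_trains(method: str = ev.PEAK_PRESSURE,
                          rate: float = 96000.0):
    """Synthesize the four tones and return normalized pulse trains.

    Returns ``(trains, stimuli, contours)``; amplitudes are normalized to
    a grand mean of 1 across the four trains.
    """
    contours = [make_f0_contour(t) for t in TONE_IDS]
    stimuli = [synth_tone(c, rate=rate) for c in contours]
    detect = (ev.detect_cycle_events_glottal if method == ev.GLOTTAL_PULSE
              else ev.detect_cycle_events_peak)
    trains = ev.normalize_amplitudes([detect(s, c)
                                      for s, c in zip(stimuli, contours)])
    return trains, stimuli, contours


def predictions_on_epoch(model, trains, avg: AverageResponse) -> list:
    """Per-stimulus predictions placed on the full epoch clock.

    The model predicts from stimulus onset onward; samples before onset
    are zero.  Shapes match ``avg.get(stimulus_id, component)``.
    """
    t = avg.times_ms
    pre = int(np.sum(t < 0))
    n_post = len(t) - pre
    preds = model.predict(trains, n_post)
    out = []
    for p in preds:
        p2 = np.atleast_2d(p)
        full = np.zeros((p2.shape[0], len(t)))
        full[:, pre:] = p2
        out.append(full)
    return out


def evaluate_fit(model, trains, avg: AverageResponse, component: str = ENV,
                 bands: dict | None = None,
                 band_window_ms=metrics.SUSTAINED_WINDOW_MS) -> dict:
    """Pooled fit metrics of a fitted model against averaged responses.

    Returns variance-explained reports for the full (0-280 ms), sustained
    (50-250 ms) and onset (0-50 ms) windows, plus band-resolved reports.
    """
    t = avg.times_ms
    data = [avg.get(tr.stimulus_id, component) for tr in trains]
    preds = predictions_on_epoch(model, trains, avg)
    reports = {
        "full": metrics.pooled_variance_explained(data, preds, t,
                                                  metrics.FULL_WINDOW_MS),
        "sustained": metrics.pooled_variance_explained(
            data, preds, t, metrics.SUSTAINED_WINDOW_MS),
        "onset": metrics.pooled_variance_explained(data, preds, t,
                                                   metrics.ONSET_WINDOW_MS),
    }
    band_reports = {}
    for d, p in zip(data, preds):
        br = metrics.band_variance_explained(d[0], p[0], t, avg.rate,
                                             bands=bands,
                                             window_ms=band_window_ms)
        for name, rep in br.items():
            band_reports.setdefault(name, []).append(rep)
    reports["bands"] = {
        name: metrics.VarianceReport(
            tms=float(np.mean([r.tms for r in reps])),
            rms=float(np.mean([r.rms for r in reps])),
            bms=float(np.mean([r.bms for r in reps])),
            window_ms=reps[0].window_ms)
        for name, reps in band_reports.items()}
    return reports


def fit_linear(avg: AverageResponse, trains, component: str = ENV,
               **params) -> KernelDeconvolver:
    """Fit the plain linear deconvolution model to averaged responses."""
    return KernelDeconvolver(**params).fit(
        trains, _responses_for(avg, trains, component))


def fit_adaptive(avg: AverageResponse, trains, component: str = ENV,
                 **params) -> AdaptiveDeconvolver:
    """Fit the nonlinear-linear (adaptation + onset) model."""
    return AdaptiveDeconvolver(**params).fit(
        trains, _responses_for(avg, trains, component))
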