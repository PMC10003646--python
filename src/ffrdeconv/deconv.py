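"""Linear deconvolution of the FFR by lagged-Dirac regression.

Under the superposition hypothesis the frequency-following response is the
convolution of a short impulse response (the "F0 response" or kernel) with
the train of F0-cycle events.  The kernel is recovered by ordinary least
squares on a design matrix whose columns are the pulse trains shifted in
steps of one sample (0.1 ms at the 10 kHz analysis rate); responses to all
stimuli are concatenated with invalid gap rows between blocks so that no
stimulus leaks into the next.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from sklearn.base import BaseEstimator

from .events import PulseTrain, shuffle_rotate
from .preprocess import ENV, AverageResponse, EpochSet, average_responses

DEFAULT_LAG_SPAN_MS = 80.0
DEFAULT_RATE = 10000.0


class RankDeficientDesignError(np.linalg.LinAlgError):
    """The lag design does not admit a unique kernel (aliased lags).

    Typical cause: a single constant-F0 stimulus, where a lag and the lag
    one F0 period later are (nearly) indistinguishable.  A stimulus set
    with a wide range of fundamental frequencies removes the ambiguity.
    """


@dataclass
class DesignMatrix:
    """Sparse lagged-Dirac design with gap rows flagged invalid.

    ``X`` holds one row per concatenated time sample; ``valid`` marks rows
    that belong to a stimulus block (gap rows between blocks are excluded
    from fitting); ``blocks`` maps stimulus ids to row slices.
    """

    X: scipy.sparse.csr_matrix
    valid: np.ndarray
    blocks: list = field(default_factory=list)  # (stimulus_id, slice)
    lags_ms: np.ndarray = None
    n_lag_cols: int = 0
    has_onset: bool = False

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


def build_design(trains: list[PulseTrain], n_samples: int,
                 lag_span_ms: float = DEFAULT_LAG_SPAN_MS,
                 rate: float = DEFAULT_RATE,
                 include_onset: bool = False) -> DesignMatrix:
    """Assemble the concatenated lagged design for a set of pulse trains.

    Each stimulus contributes a block of ``n_samples`` rows (its response
    duration at ``rate``); column j of that block is the block's pulse
    train shifted by j samples.  With ``include_onset`` a second bank of
    lagged columns is driven by a unit pulse at each stimulus's first
    event, modeling a qualitatively distinct stimulus-onset response.
    Blocks are separated by one lag span of invalid gap rows.
    """
    if not trains:
        raise ValueError("need at least one pulse train")
    n_lags = lag_span_ms * rate / 1000.0
    if abs(n_lags - round(n_lags)) > 1e-9:
        raise ValueError("lag span must be an integer number of samples")
    n_lags = int(round(n_lags))
    gap = n_lags
    n_cols = n_lags * (2 if include_onset else 1)
    rows_per = n_samples + gap
    n_rows = rows_per * len(trains) - gap
    rix, cix, vals = [], [], []
    valid = np.zeros(n_rows, dtype=bool)
    blocks = []
    lag_idx = np.arange(n_lags)
    for b, train in enumerate(trains):
        r0 = b * rows_per
        valid[r0:r0 + n_samples] = True
        blocks.append((train.stimulus_id, slice(r0, r0 + n_samples)))
        samp = np.round(train.onsets_ms / 1000.0 * rate).astype(int)
        if np.any(samp < 0) or np.any(samp >= n_samples):
            raise ValueError("pulse outside the block time range")
        pulse_sets = [(samp, train.amplitudes, 0)]
        if include_onset:
            pulse_sets.append((samp[:1], np.ones(1), n_lags))
        for s, a, col0 in pulse_sets:
            rr = (r0 + s[:, None] + lag_idx[None, :]).ravel()
            cc = np.broadcast_to(col0 + lag_idx, (len(s), n_lags)).ravel()
            vv = np.broadcast_to(a[:, None], (len(s), n_lags)).ravel()
            keep = rr < r0 + n_samples
            rix.append(rr[keep])
            cix.append(cc[keep])
            vals.append(vv[keep])
    X = scipy.sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rix), np.concatenate(cix))),
        shape=(n_rows, n_cols)).tocsr()
    return DesignMatrix(X=X, valid=valid, blocks=blocks,
                        lags_ms=lag_idx / rate * 1000.0,
                        n_lag_cols=n_lags, has_onset=include_onset)


@dataclass
class Kernel:
    """Lag-indexed kernel weights (microvolts per unit pulse amplitude)."""

    lags_ms: np.ndarray
    weights: np.ndarray  # (n_lags,) or (n_channels, n_lags)
    response_type: str = ENV
    meta: dict = field(default_factory=dict)


def _stack_responses(responses, n_design_rows, blocks, valid):
    """Concatenate per-block responses into the design's row space."""
    ys = [np.atleast_2d(np.asarray(r, dtype=float)) for r in responses]
    n_ch = ys[0].shape[0]
    Y = np.zeros((n_design_rows, n_ch))
    for (sid, sl), y in zip(blocks, ys):
        if y.shape[1] != sl.stop - sl.start:
            raise ValueError(f"response for {sid} has {y.shape[1]} samples, "
                             f"block expects {sl.stop - sl.start}")
        Y[sl] = y.T
    return Y, n_ch


class KernelDeconvolver(BaseEstimator):
    """Estimate the per-F0-cycle kernel of an FFR by lagged regression.

    A single kernel jointly explains the responses to all stimuli in the
    set.  ``fit`` expects a list of :class:`PulseTrain` and a matching list
    of response waveforms (``(n_times,)`` or ``(n_channels, n_times)``,
    sample 0 at stimulus onset, in microvolts).

    Parameters
    ----------
    lag_span_ms : float
        Kernel duration; 80 ms at 10 kHz gives 800 lag regressors.
    rate : float
        Analysis sampling rate in Hz.
    include_onset : bool
        Add a second lagged regressor bank driven by each stimulus's first
        event (stimulus-onset response).
    solver : {"normal", "direct"}
        "normal" solves the normal equations of the sparse design (fast);
        "direct" runs dense SVD least squares on the valid rows.
    ridge : float
        Optional Tikhonov penalty for ill-conditioned user data; 0 keeps
        the plain linear model.
    cond_max : float
        Condition-number threshold above which the design is treated as
        not admitting a unique solution.
    collinearity_max : float
        Maximum tolerated correlation between two lag columns.  Stimuli
        with a (nearly) constant F0 make lags one period apart almost
        indistinguishable; a wide F0 range keeps this low.
    on_ill_conditioned : {"raise", "warn"}
        What to do when either threshold is exceeded (ridge disables the
        check).

    Attributes
    ----------
    kernel_ : ndarray
        Fitted lag weights, ``(n_lags,)`` or ``(n_channels, n_lags)``.
    onset_kernel_ : ndarray or None
        Onset-response weights when ``include_onset``.
    lags_ms_ : ndarray
        Lag grid in ms.
    rank_, cond_ : int, float
        Numerical rank and condition number of the valid-row design.
    """

    def __init__(self, lag_span_ms: float = DEFAULT_LAG_SPAN_MS,
                 rate: float = DEFAULT_RATE, include_onset: bool = False,
                 solver: str = "normal", ridge: float = 0.0,
                 cond_max: float = 1e8, collinearity_max: float = 0.95,
                 on_ill_conditioned: str = "raise"):
        self.lag_span_ms = lag_span_ms
        self.rate = rate
        self.include_onset = include_onset
        self.solver = solver
        self.ridge = ridge
        self.cond_max = cond_max
        self.collinearity_max = collinearity_max
        self.on_ill_conditioned = on_ill_conditioned

    def fit(self, trains: list[PulseTrain], responses) -> "KernelDeconvolver":
        design = build_design(trains, n_samples=np.atleast_2d(responses[0]).shape[-1],
                              lag_span_ms=self.lag_span_ms, rate=self.rate,
                              include_onset=self.include_onset)
        Y, n_ch = _stack_responses(responses, design.X.shape[0],
                                   design.blocks, design.valid)
        Xv = design.X[design.valid]
        Yv = Y[design.valid]
        if Xv.shape[0] < design.n_cols:
            raise ValueError("fewer valid samples than regressors")
        G = (Xv.T @ Xv).toarray()
        if self.solver == "direct":
            B, _, rank, sv = scipy.linalg.lstsq(Xv.toarray(), Yv,
                                                lapack_driver="gelsd")
            cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        elif self.solver == "normal":
            if self.ridge > 0:
                G = G + self.ridge * np.eye(G.shape[0])
            b = Xv.T @ Yv
            try:
                # Cholesky + LAPACK condition estimate: fast path for the
                # well-posed case (the inner loop of the adaptation fit)
                cf = scipy.linalg.cho_factor(G)
                B = scipy.linalg.cho_solve(cf, b)
                anorm = np.linalg.norm(G, 1)
                rcond, info = scipy.linalg.lapack.dpocon(cf[0], anorm)
                cond = np.sqrt(1.0 / rcond) if (info == 0 and rcond > 0) else np.inf
                rank = G.shape[0]
            except np.linalg.LinAlgError:
                ev = scipy.linalg.eigh(G, eigvals_only=True)
                lo, hi = max(ev[0], 0.0), ev[-1]
                cond = np.sqrt(hi / lo) if lo > 0 else np.inf
                rank = int(np.sum(ev > hi * G.shape[0] * np.finfo(float).eps))
                B, *_ = scipy.linalg.lstsq(G, b)
        else:
            raise ValueError(f"unknown solver {self.solver!r}")
        self.rank_ = rank
        self.cond_ = float(cond)
        norms = np.sqrt(np.diag(G))
        corr = G / np.maximum(np.outer(norms, norms), np.finfo(float).tiny)
        np.fill_diagonal(corr, 0.0)
        self.max_collinearity_ = float(np.max(np.abs(corr)))
        if self.ridge == 0 and (rank < design.n_cols or cond > self.cond_max
                                or self.max_collinearity_
                                > self.collinearity_max):
            msg = (f"lag design does not constrain a unique kernel "
                   f"(rank {rank}/{design.n_cols}, cond {cond:.3g}, max column "
                   f"correlation {self.max_collinearity_:.3f}): lags one F0 "
                   "period apart are aliased; use stimuli with a wider F0 "
                   "range or ridge > 0")
            if self.on_ill_conditioned == "raise":
                raise RankDeficientDesignError(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        B = B.T  # (n_ch, n_cols)
        n_lags = design.n_lag_cols
        kern = B[:, :n_lags]
        self.kernel_ = kern[0] if n_ch == 1 else kern
        if self.include_onset:
            onset = B[:, n_lags:]
            self.onset_kernel_ = onset[0] if n_ch == 1 else onset
        else:
            self.onset_kernel_ = None
        self.lags_ms_ = design.lags_ms
        self.n_channels_ = n_ch
        self.design_ = design
        return self

    def predict(self, trains: list[PulseTrain], n_samples: int | None = None):
        """Forward-convolve the fitted kernel with pulse trains.

        Returns one waveform per train (same channel layout as ``fit``).
        """
        if not hasattr(self, "kernel_"):
            raise RuntimeError("estimator is not fitted")
        kern = np.atleast_2d(self.kernel_)
        onset = (np.atleast_2d(self.onset_kernel_)
                 if self.onset_kernel_ is not None else None)
        if n_samples is None:
            n_samples = self.design_.blocks[0][1].stop - self.design_.blocks[0][1].start
        out = []
        for train in trains:
            y = predict_waveform(kern, train, n_samples, self.rate,
                                 onset_kernel=onset)
            out.append(y[0] if self.n_channels_ == 1 else y)
        return out

    def residual_ss(self, trains, responses) -> float:
        """Sum of squared residuals over all stimuli and channels."""
        preds = self.predict(trains, np.atleast_2d(responses[0]).shape[-1])
        return float(sum(np.sum((np.atleast_2d(r) - np.atleast_2d(p)) ** 2)
                         for r, p in zip(responses, preds)))

    def score(self, trains, responses) -> float:
        """Plain (uncorrected) R^2 of the concatenated prediction."""
        preds = self.predict(trains, np.atleast_2d(responses[0]).shape[-1])
        y = np.concatenate([np.atleast_2d(r).ravel() for r in responses])
        p = np.concatenate([np.atleast_2d(q).ravel() for q in preds])
        return 1.0 - np.sum((y - p) ** 2) / np.sum((y - np.mean(y)) ** 2)

    def to_kernel(self, response_type: str = ENV, **meta) -> Kernel:
        return Kernel(lags_ms=self.lags_ms_, weights=self.kernel_,
                      response_type=response_type, meta=meta)


def predict_waveform(kernel: np.ndarray, train: PulseTrain, n_samples: int,
                     rate: float = DEFAULT_RATE,
                     onset_kernel: np.ndarray | None = None) -> np.ndarray:
    """Superpose kernel copies at the train's events: channels x time."""
    kern = np.atleast_2d(kernel)
    y = np.zeros((kern.shape[0], n_samples))
    samp = np.round(train.onsets_ms / 1000.0 * rate).astype(int)
    n_lags = kern.shape[1]
    for s, a in zip(samp, train.amplitudes):
        hi = min(s + n_lags, n_samples)
        if s < n_samples:
            y[:, s:hi] += a * kern[:, :hi - s]
    if onset_kernel is not None and len(samp):
        ok = np.atleast_2d(onset_kernel)
        s = samp[0]
        hi = min(s + ok.shape[1], n_samples)
        y[:, s:hi] += ok[:, :hi - s]
    return y


def fit_kernel(trains, responses, **params) -> KernelDeconvolver:
    """Functional wrapper around :class:`KernelDeconvolver`."""
    return KernelDeconvolver(**params).fit(trains, responses)


def _responses_for(avg: AverageResponse, trains, component):
    """Extract per-train post-onset waveforms from an average response."""
    t = avg.times_ms
    sel = t >= 0.0
    return [avg.get(tr.stimulus_id, component)[:, sel] for tr in trains]


def crossval(epochs: EpochSet, trains: list[PulseTrain], scheme: str,
             component: str = ENV, sessions: list[AverageResponse] | None = None,
             rng: np.random.Generator | None = None, **deconv_params) -> dict:
    """Overfitting controls: split-half, cross-session, and shuffle schemes.

    ``split_half`` randomly halves the trials of each condition, fits on
    the first half's averages and predicts the second half's.
    ``cross_session`` (needs ``sessions``: one :class:`AverageResponse` per
    recording session) predicts each session with kernels fitted on every
    other session.  ``shuffle`` fits and predicts with cyclically rotated
    pulse trains, a mismatch control for the large number of regressors.
    Returns fitted models, held-out averages, and predictions; fit metrics
    are computed downstream.
    """
    rng = rng or np.random.default_rng()
    if scheme == "split_half":
        mask = np.zeros(epochs.n_trials, dtype=bool)
        for sid in np.unique(epochs.stimulus_ids):
            for pol in np.unique(epochs.polarities):
                idx = np.flatnonzero((epochs.stimulus_ids == sid)
                                     & (epochs.polarities == pol))
                half = rng.permutation(idx)[:len(idx) // 2]
                mask[half] = True
        halves = []
        for m in (mask, ~mask):
            sub = EpochSet(data=epochs.data[m], rate=epochs.rate,
                           t_start_ms=epochs.t_start_ms,
                           stimulus_ids=epochs.stimulus_ids[m],
                           polarities=epochs.polarities[m],
                           rejected=epochs.rejected[m])
            halves.append(average_responses(sub))
        train_avg, test_avg = halves
        model = KernelDeconvolver(**deconv_params).fit(
            trains, _responses_for(train_avg, trains, component))
        preds = model.predict(trains)
        return {"model": model, "train_avg": train_avg, "test_avg": test_avg,
                "test_responses": _responses_for(test_avg, trains, component),
                "predictions": preds}
    if scheme == "cross_session":
        if not sessions or len(sessions) < 2:
            raise ValueError("cross_session needs >=2 sessions")
        out = []
        for i, test in enumerate(sessions):
            models = [KernelDeconvolver(**deconv_params).fit(
                trains, _responses_for(s, trains, component))
                for j, s in enumerate(sessions) if j != i]
            out.append({"test_avg": test,
                        "test_responses": _responses_for(test, trains, component),
                        "models": models,
                        "predictions": [m.predict(trains) for m in models]})
        return {"sessions": out}
    if scheme == "shuffle":
        avg = average_responses(epochs)
        rotated = shuffle_rotate(trains)
        model = KernelDeconvolver(**deconv_params).fit(
            rotated, _responses_for(avg, rotated, component))
        return {"model": model, "test_avg": avg,
                "test_responses": _responses_for(avg, rotated, component),
                "predictions": model.predict(rotated)}
    raise ValueError(f"unknown crossval scheme {scheme!r}")
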