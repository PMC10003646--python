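"""Lagged-design construction, kernel estimation, prediction, cross-validation."""

import numpy as np
import pytest

from ffrdeconv.deconv import (KernelDeconvolver, RankDeficientDesignError,
                              build_design, crossval, predict_waveform)
from ffrdeconv.events import PulseTrain
from ffrdeconv.metrics import SUSTAINED_WINDOW_MS, kernel_similarity
from ffrdeconv.preprocess import average_responses
from ffrdeconv.simulate import GroundTruthConfig, simulate_session


def toy_train(sid="a", onsets=(0.0, 12.0, 27.0), amps=None):
    onsets = np.asarray(onsets, dtype=float)
    amps = np.ones_like(onsets) if amps is None else np.asarray(amps, float)
    return PulseTrain(sid, onsets, amps)


class TestBuildDesign:
    def test_default_span_gives_800_lag_columns(self):
        d = build_design([toy_train()], n_samples=500, lag_span_ms=80.0,
                         rate=10000.0)
        assert d.n_cols == 800
        assert d.n_lag_cols == 800
        assert d.lags_ms[-1] == pytest.approx(79.9)

    def test_dual_regressor_45ms_gives_900_columns(self):
        d = build_design([toy_train()], n_samples=500, lag_span_ms=45.0,
                         rate=10000.0, include_onset=True)
        assert d.n_cols == 900

    def test_single_pulse_identity_strip(self):
        d = build_design([toy_train(onsets=(0.0,))], n_samples=10,
                         lag_span_ms=1.0, rate=10000.0)
        np.testing.assert_array_equal(d.X.toarray()[d.valid], np.eye(10))

    def test_gap_rows_flagged_invalid(self):
        d = build_design([toy_train("a"), toy_train("b")], n_samples=400,
                         lag_span_ms=2.0, rate=10000.0)
        assert d.valid.sum() == 800
        assert (~d.valid).sum() == 20  # one gap of one lag span

    def test_column_is_shifted_pulse_train(self):
        train = toy_train(onsets=(1.0, 3.0), amps=(2.0, 0.5))
        d = build_design([train], n_samples=60, lag_span_ms=2.0, rate=10000.0)
        X = d.X.toarray()
        j = 7  # lag 0.7 ms
        expected = np.zeros(60)
        expected[10 + j] = 2.0
        expected[30 + j] = 0.5
        np.testing.assert_array_equal(X[:, j], expected)

    def test_pulse_outside_block_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_design([toy_train(onsets=(90.0,))], n_samples=100,
                         lag_span_ms=2.0, rate=10000.0)


class TestFitKernel:
    def make_problem(self, rng, n_ch=1, solver="normal"):
        trains = [toy_train("a", (0.0, 11.0, 23.0, 37.0), (1.0, 0.8, 1.2, 0.9)),
                  toy_train("b", (2.0, 15.0, 31.0), (1.1, 1.0, 0.7))]
        true = rng.standard_normal((n_ch, 30))
        n_samples = 800
        responses = [predict_waveform(true, t, n_samples) for t in trains]
        if n_ch == 1:
            responses = [r[0] for r in responses]
        model = KernelDeconvolver(lag_span_ms=3.0, solver=solver).fit(
            trains, responses)
        return model, true, trains, responses

    @pytest.mark.parametrize("solver", ["normal", "direct"])
    def test_noise_free_exact_recovery(self, rng, solver):
        model, true, _, _ = self.make_problem(rng, solver=solver)
        err = np.max(np.abs(model.kernel_ - true[0]))
        assert err < 1e-8 * np.max(np.abs(true))

    def test_multichannel_recovery(self, rng):
        model, true, _, _ = self.make_problem(rng, n_ch=3)
        assert model.kernel_.shape == (3, 30)
        np.testing.assert_allclose(model.kernel_, true, atol=1e-8)

    def test_matches_brute_force_normal_equations(self, rng):
        """Oracle: dense normal-equations solve on a <=200-sample problem."""
        trains = [toy_train("a", (0.0, 4.5, 11.0), (1.0, 0.6, 1.3))]
        n_samples = 180
        y = rng.standard_normal(n_samples)
        model = KernelDeconvolver(lag_span_ms=2.0, solver="normal").fit(
            trains, [y])
        # independent dense construction of the shifted-impulse design
        X = np.zeros((n_samples, 20))
        for j in range(20):
            for onset, amp in zip(trains[0].onsets_ms, trains[0].amplitudes):
                s = int(round(onset * 10)) + j
                if s < n_samples:
                    X[s, j] += amp
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.kernel_, ref, rtol=1e-10, atol=1e-12)

    def test_predict_fit_consistency(self, rng):
        model, _, trains, responses = self.make_problem(rng)
        preds = model.predict(trains, len(responses[0]))
        for p, r in zip(preds, responses):
            np.testing.assert_allclose(p, r, atol=1e-8)

    def test_constant_f0_design_flagged_nonunique(self):
        """A single constant-F0 train aliases lags one period apart."""
        onsets = np.arange(0.0, 240.0, 10.0)  # constant 100 Hz
        train = toy_train("a", onsets)
        d = build_design([train], n_samples=3300, lag_span_ms=20.0)
        # brute force: lag columns one F0 period apart are nearly identical
        X = d.X.toarray()[d.valid]
        Xn = X / np.linalg.norm(X, axis=0)
        corr = Xn.T @ Xn
        np.fill_diagonal(corr, 0.0)
        assert corr.max() > 0.95
        assert corr[0, 100] > 0.95  # lag 0 vs lag 10 ms = one period
        with pytest.raises(RankDeficientDesignError):
            KernelDeconvolver(lag_span_ms=20.0).fit([train],
                                                    [np.ones(3300)])

    def test_wide_f0_range_well_conditioned(self, trains, default_avg):
        model = KernelDeconvolver(lag_span_ms=80.0).fit(
            trains, [default_avg.get(t.stimulus_id, "ENV")[:, 500:]
                     for t in trains])
        assert model.rank_ == 800
        assert model.cond_ < 1e4


class TestPredict:
    def test_unit_pulse_returns_kernel(self):
        k = np.sin(np.linspace(0, 3, 40))
        train = toy_train(onsets=(0.0,))
        y = predict_waveform(k, train, 100)[0]
        np.testing.assert_allclose(y[:40], k)
        np.testing.assert_allclose(y[40:], 0.0)

    def test_linearity_in_amplitude(self):
        k = np.sin(np.linspace(0, 3, 40))
        t1 = toy_train(onsets=(0.0, 9.0), amps=(1.0, 2.0))
        t2 = toy_train(onsets=(0.0, 9.0), amps=(2.0, 4.0))
        np.testing.assert_allclose(2 * predict_waveform(k, t1, 200),
                                   predict_waveform(k, t2, 200))


class TestCrossval:
    def test_split_half_on_identical_halves(self, rng):
        from ffrdeconv.preprocess import EpochSet
        k = rng.standard_normal(25)
        trains = [toy_train(f"s{i}", np.sort(rng.uniform(0, 80, 6)))
                  for i in range(2)]
        waves = [predict_waveform(k, t, 1000)[0] for t in trains]
        data, sids, pols = [], [], []
        for t, w in zip(trains, waves):
            for pol in ("condensation", "rarefaction"):
                data.append(np.tile(w, (8, 1, 1)))
                sids += [t.stimulus_id] * 8
                pols += [pol] * 8
        epochs = EpochSet(data=np.concatenate(data), rate=10000.0,
                          t_start_ms=0.0, stimulus_ids=np.array(sids),
                          polarities=np.array(pols))
        out = crossval(epochs, trains, "split_half", lag_span_ms=2.5, rng=rng)
        for p, r in zip(out["predictions"], out["test_responses"]):
            np.testing.assert_allclose(p, r[0], atol=1e-8)

    def test_cross_session_identical_sessions(self, trains, default_avg):
        out = crossval(None, trains, "cross_session",
                       sessions=[default_avg, default_avg], lag_span_ms=45.0,
                       include_onset=True)
        k0 = out["sessions"][0]["models"][0].kernel_
        k1 = out["sessions"][1]["models"][0].kernel_
        assert kernel_similarity(k0, k1) == pytest.approx(1.0)

    def test_single_session_cross_session_rejected(self, trains, default_avg):
        with pytest.raises(ValueError, match=">=2"):
            crossval(None, trains, "cross_session", sessions=[default_avg])


class TestRecoveryFromSimulation:
    def test_kernel_recovery_under_noise(self, trains, default_session,
                                         default_avg):
        """Full-scale noisy session: recovered kernel matches ground truth."""
        _, gt = default_session
        model = KernelDeconvolver(lag_span_ms=45.0, include_onset=True).fit(
            trains, [default_avg.get(t.stimulus_id, "ENV")[:, 500:]
                     for t in trains])
        assert kernel_similarity(model.kernel_, gt["kernel"]) > 0.95

    def test_split_half_reliability(self, trains, default_session):
        epochs, gt = default_session
        rng = np.random.default_rng(0)
        out = crossval(epochs, trains, "split_half", lag_span_ms=45.0,
                       include_onset=True, rng=rng)
        assert kernel_similarity(out["model"].kernel_, gt["kernel"]) > 0.95
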