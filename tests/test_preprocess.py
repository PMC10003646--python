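"""Filtering, epoching, artifact rejection, polarity algebra, baseline QC."""

import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from ffrdeconv.preprocess import (ENV, TFS, EpochSet, average_responses,
                                  bandpass_zero_phase, baseline_noise_qc,
                                  epoch_downsample, reject_artifacts)


def make_epochs(data, sids=None, pols=None, rate=10000.0, t_start=-50.0):
    n = data.shape[0]
    return EpochSet(data=data, rate=rate, t_start_ms=t_start,
                    stimulus_ids=np.array(sids if sids is not None
                                          else ["T1"] * n),
                    polarities=np.array(pols if pols is not None
                                        else ["condensation"] * n))


class TestBandpass:
    rate = 30000.0

    def test_dc_removed(self):
        out = bandpass_zero_phase(np.full(30000, 5.0), rate=self.rate)
        assert np.abs(np.mean(out[5000:-5000])) < 1e-3

    def test_passband_tone_preserved(self):
        t = np.arange(30000) / self.rate
        out = bandpass_zero_phase(np.sin(2 * np.pi * 1000.0 * t),
                                  rate=self.rate)
        amp = np.max(np.abs(out[10000:20000]))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_matches_filter_response(self):
        # oracle: squared (two-pass) Butterworth magnitude at 10 Hz
        sos = butter(2, [60.0, 2000.0], btype="bandpass", fs=self.rate,
                     output="sos")
        _, h = sosfreqz(sos, worN=[2 * np.pi * 10.0 / self.rate])
        expected = np.abs(h[0]) ** 2
        assert expected < 0.1  # >90% attenuation predicted
        t = np.arange(90000) / self.rate
        out = bandpass_zero_phase(np.sin(2 * np.pi * 10.0 * t), rate=self.rate)
        measured = np.max(np.abs(out[30000:60000]))
        assert measured == pytest.approx(expected, rel=0.25)

    def test_zero_phase_no_peak_shift(self):
        x = np.zeros(30000)
        x[15000] = 1.0
        sym = np.convolve(x, np.hanning(301), mode="same")  # symmetric pulse
        out = bandpass_zero_phase(sym, rate=self.rate)
        assert abs(int(np.argmax(out)) - 15000) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(100), high=20000.0, rate=self.rate)


class TestEpochDownsample:
    def test_shape_arithmetic(self):
        raw = np.zeros((2, 90000))
        out = epoch_downsample(raw, 30000.0, [10000, 40000],
                               window_ms=(-50.0, 390.0), target_rate=10000.0)
        assert out.shape == (2, 2, 4400)

    def test_no_triggers_gives_empty(self):
        out = epoch_downsample(np.zeros((1, 1000)), 30000.0, [])
        assert out.shape[0] == 0

    def test_impulse_lands_in_t0_bin(self):
        raw = np.zeros((1, 90000))
        raw[0, 40000] = 1.0
        out = epoch_downsample(raw, 30000.0, [40000],
                               window_ms=(-50.0, 390.0), target_rate=10000.0)
        t0_bin = 500  # 50 ms pre-stimulus at 10 kHz
        assert abs(int(np.argmax(np.abs(out[0, 0]))) - t0_bin) <= 1

    def test_out_of_bounds_trigger_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            epoch_downsample(np.zeros((1, 1000)), 30000.0, [100])

    def test_noninteger_decimation_rejected(self):
        with pytest.raises(ValueError):
            epoch_downsample(np.zeros((1, 90000)), 30000.0, [10000],
                             target_rate=7000.0)


class TestArtifactRejection:
    def base(self, n=40, n_ch=4, n_t=100):
        rng = np.random.default_rng(0)
        return 0.1 * rng.standard_normal((n, n_ch, n_t))

    def test_identical_epochs_keep_all(self):
        data = np.tile(np.sin(np.linspace(0, 10, 100)), (20, 3, 1))
        out = reject_artifacts(make_epochs(data))
        assert not out.rejected.any()

    def test_single_channel_outlier_masked_locally(self):
        data = self.base()
        data[5, 2] *= 100.0
        out = reject_artifacts(make_epochs(data))
        assert out.rejected[5, 2]
        assert out.rejected[5].sum() == 1
        assert out.rejected.sum() == 1

    def test_multichannel_outlier_masked_everywhere(self):
        data = self.base()
        data[5, :3] *= 100.0
        out = reject_artifacts(make_epochs(data))
        assert out.rejected[5].all()

    def test_data_untouched(self):
        data = self.base()
        data[5, 2] *= 100.0
        epochs = make_epochs(data)
        out = reject_artifacts(epochs)
        np.testing.assert_array_equal(out.data, data)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError, match=">=10"):
            reject_artifacts(make_epochs(self.base(n=5)))


class TestAveraging:
    def test_env_tfs_identities(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((1, 200))
        same = np.concatenate([np.tile(w, (10, 1, 1)), np.tile(w, (10, 1, 1))])
        sids = ["T1"] * 20
        pols = ["condensation"] * 10 + ["rarefaction"] * 10
        avg = average_responses(make_epochs(same, sids, pols))
        np.testing.assert_allclose(avg.get("T1", TFS), 0.0, atol=1e-14)
        np.testing.assert_allclose(avg.get("T1", ENV), w)
        anti = np.concatenate([np.tile(w, (10, 1, 1)),
                               np.tile(-w, (10, 1, 1))])
        avg = average_responses(make_epochs(anti, sids, pols))
        np.testing.assert_allclose(avg.get("T1", ENV), 0.0, atol=1e-14)
        np.testing.assert_allclose(avg.get("T1", TFS), w)

    def test_env_plus_tfs_reconstructs_condensation(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((24, 2, 150))
        sids = ["T1"] * 12 + ["T2"] * 12
        pols = (["condensation"] * 6 + ["rarefaction"] * 6) * 2
        avg = average_responses(make_epochs(data, sids, pols))
        for sid in ("T1", "T2"):
            np.testing.assert_allclose(
                avg.get(sid, ENV) + avg.get(sid, TFS),
                avg.get(sid, "condensation"), atol=1e-12)

    def test_rejected_trials_excluded(self):
        data = np.zeros((10, 1, 50))
        data[0] = 100.0
        epochs = make_epochs(data, ["T1"] * 10,
                             ["condensation"] * 5 + ["rarefaction"] * 5)
        epochs.rejected[0, 0] = True
        avg = average_responses(epochs)
        np.testing.assert_allclose(avg.get("T1", "condensation"), 0.0)
        assert avg.n_trials[("T1", "condensation")][0] == 4

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="no trials"):
            average_responses(make_epochs(np.zeros((10, 1, 50)),
                                          ["T1"] * 10, ["condensation"] * 10))


class TestBaselineQC:
    def make_avg(self, level):
        rng = np.random.default_rng(3)
        n_t = 4400
        data = []
        sids, pols = [], []
        for sid in ("T1", "T2", "T3", "T4"):
            for pol in ("condensation", "rarefaction"):
                w = np.sqrt(level) * rng.standard_normal((1, 1, n_t))
                data.append(w)
                sids.append(sid)
                pols.append(pol)
        return average_responses(make_epochs(
            np.concatenate(data), sids, pols))

    def test_zero_baseline_passes(self):
        avg = average_responses(make_epochs(
            np.zeros((8, 1, 4400)), ["T1", "T2", "T3", "T4"] * 2,
            ["condensation"] * 4 + ["rarefaction"] * 4))
        noise, ok = baseline_noise_qc(avg)
        assert noise == 0.0 and ok

    def test_noise_level_estimated_consistently(self):
        avg = self.make_avg(0.02)
        noise, ok = baseline_noise_qc(avg)
        # ENV of two independent trials halves the variance
        assert noise == pytest.approx(0.01, rel=0.25)
        assert not ok

    def test_threshold_is_strict(self):
        avg = self.make_avg(0.02)
        noise, ok = baseline_noise_qc(avg, threshold_uv2=noise_exact(avg))
        assert not ok


def noise_exact(avg):
    noise, _ = baseline_noise_qc(avg)
    return noise


def test_averaging_reduces_baseline_noise_inverse_n(trains, default_session):
    """Averaging n independent noise realizations scales power by ~1/n."""
    epochs, _ = default_session
    avg = average_responses(epochs)
    noise, ok = baseline_noise_qc(avg)
    per_trial = 1.5 ** 2  # simulator per-trial noise RMS is 1.5 uV
    n_env = 1000          # 500 trials per polarity enter each ENV average
    assert ok
    assert noise == pytest.approx(per_trial / n_env, rel=0.2)
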