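import numpy as np
import pytest
from scipy.signal import hilbert

from eegfmri.features import DEFAULT_BANDS
from eegfmri.hrf import HRFParams, hrf_kernel, scaled_params
from eegfmri.synth import (
    NEURAL_DT_S,
    GroundTruth,
    GroupConfig,
    generate_group,
    inject_motion,
    simulate_bold,
    simulate_eeg,
    simulate_neural_rsn,
    simulate_subject,
)


class TestNeuralDrivers:
    def test_deterministic_given_seed(self):
        a = simulate_neural_rsn(3, 300.0, seed=5)
        b = simulate_neural_rsn(3, 300.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_rows_standardized(self):
        x = simulate_neural_rsn(2, 600.0, dt_s=0.1, seed=1)
        assert x.shape == (2, 6000)
        np.testing.assert_allclose(x.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(x.var(axis=1), 1.0, atol=0.05)

    def test_power_concentrated_in_band_fft_oracle(self):
        x = simulate_neural_rsn(2, 600.0, dt_s=0.1, seed=2)
        f = np.fft.rfftfreq(x.shape[1], d=0.1)
        spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
        inside = spec[:, (f >= 0.01) & (f <= 0.1)].sum(axis=1)
        assert np.all(inside / spec.sum(axis=1) >= 0.95)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_neural_rsn(2, -1.0)
        with pytest.raises(ValueError):
            simulate_neural_rsn(2, 100.0, dt_s=0.1, band_lo_hz=0.2,
                                band_hi_hz=0.1)


def _truth(coupling, **kw):
    defaults = dict(true_delay=6.0,
                    region_assignment={"r0": 0}, eeg_noise_sd=0.0,
                    bold_noise_sd=0.0, seed=0)
    defaults.update(kw)
    return GroundTruth(coupling=np.asarray(coupling, dtype=float), **defaults)


class TestSimulateEEG:
    def test_zero_coupling_zero_noise_constant_band_power(self):
        from eegfmri.features import band_power_series

        neural = simulate_neural_rsn(1, 120.0, seed=3)
        truth = _truth(np.zeros((1, 5)))
        src, _ = simulate_eeg(neural, truth, DEFAULT_BANDS, 250.0,
                              sensor_noise_sd=0.0, seed=4)
        bp = band_power_series(src, ["r0"], 250.0, 2.0, space="source")
        vals = bp.values[bp.valid, 0, :]       # interior epochs x band
        cv = vals.std(axis=0) / vals.mean(axis=0)
        assert np.all(cv < 0.02)

    def test_alpha_envelope_tracks_driver_hilbert_oracle(self):
        neural = simulate_neural_rsn(1, 600.0, seed=6)
        coup = np.zeros((1, 5))
        coup[0, 2] = 0.8           # alpha
        truth = _truth(coup)
        src, _ = simulate_eeg(neural, truth, DEFAULT_BANDS, 250.0,
                              sensor_noise_sd=0.0, seed=7)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [8.0, 12.0], "bandpass", fs=250.0, output="sos")
        env = np.abs(hilbert(sosfiltfilt(sos, src[0])))
        t = np.arange(src.shape[1]) / 250.0
        z = np.interp(t, np.arange(neural.shape[1]) * NEURAL_DT_S, neural[0])
        sel = slice(2500, -2500)
        r = np.corrcoef(env[sel], z[sel])[0, 1]
        assert r >= 0.7

    def test_identity_mixing_no_sensor_noise_scalp_equals_source(self):
        neural = simulate_neural_rsn(1, 60.0, seed=8)
        truth = _truth(0.3 * np.ones((1, 5)))
        src, scalp = simulate_eeg(neural, truth, DEFAULT_BANDS, 250.0,
                                  mixing_matrix=np.eye(1),
                                  sensor_noise_sd=0.0, seed=9)
        np.testing.assert_array_equal(src, scalp)

    def test_undersampled_rate_rejected(self):
        neural = simulate_neural_rsn(1, 60.0, seed=8)
        with pytest.raises(ValueError):
            simulate_eeg(neural, _truth(np.zeros((1, 5))), DEFAULT_BANDS,
                         fs=100.0)


class TestSimulateBOLD:
    def setup_method(self):
        self.kernel = hrf_kernel(scaled_params(6.0, HRFParams(dt=NEURAL_DT_S)))

    def test_zero_input_zero_output(self):
        out = simulate_bold(np.zeros((2, 3000)), self.kernel, 2.0, 0.0)
        assert out.shape == (2, 150)            # 300 s at TR 2 s
        assert np.all(out == 0)

    def test_impulse_reproduces_kernel_at_tr_grid(self):
        x = np.zeros((1, 3000))
        x[0, 0] = 1.0
        out = simulate_bold(x, self.kernel, 2.0, 0.0)
        centers = np.round((np.arange(150) + 0.5) * 2.0 / NEURAL_DT_S).astype(int)
        padded = np.zeros(3000)
        padded[:len(self.kernel.samples)] = self.kernel.samples
        np.testing.assert_allclose(out[0], padded[centers], atol=1e-12)

    def test_lag_of_peak_crosscorrelation_matches_kernel(self):
        neural = simulate_neural_rsn(1, 600.0, seed=10)
        bold = simulate_bold(neural, self.kernel, 2.0, 0.0)
        centers = np.round((np.arange(bold.shape[1]) + 0.5) * 2.0
                           / NEURAL_DT_S).astype(int)
        x = neural[0, centers]
        y = bold[0]
        lags = np.arange(0, 10)
        xc = [np.corrcoef(x[:len(x) - l], y[l:])[0, 1] for l in lags]
        peak_tr = lags[np.argmax(xc)] * 2.0
        assert abs(peak_tr - self.kernel.peak_lag_s) <= 2.0

    def test_kernel_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            simulate_bold(np.zeros((1, 100)), self.kernel, 2.0, 0.0)


class TestInjectMotion:
    def test_empty_epoch_list_is_noop(self, fast_subject):
        out, templates = inject_motion(fast_subject, [])
        np.testing.assert_array_equal(out.eeg_scalp, fast_subject.eeg_scalp)
        np.testing.assert_array_equal(out.rsn_bold, fast_subject.rsn_bold)

    def test_large_spike_exceeds_4sd_in_every_channel(self, fast_subject):
        out, _ = inject_motion(fast_subject, [7], amplitude_sd=10.0)
        spe = int(round(out.tr * out.fs))
        z = np.abs(out.eeg_scalp - out.eeg_scalp.mean(axis=1, keepdims=True)) \
            / out.eeg_scalp.std(axis=1, keepdims=True)
        assert np.all(z[:, 7 * spe:8 * spe].max(axis=1) > 4.0)

    def test_injection_is_additive_and_invertible(self, fast_subject):
        out, templates = inject_motion(fast_subject, [3, 9], amplitude_sd=8.0)
        # unmodified samples restore bitwise; burst samples to rounding only
        np.testing.assert_allclose(out.eeg_scalp - templates["eeg_scalp"],
                                   fast_subject.eeg_scalp, rtol=0, atol=1e-12)
        np.testing.assert_allclose(out.rsn_bold - templates["rsn_bold"],
                                   fast_subject.rsn_bold, rtol=0, atol=1e-12)
        spe = int(round(out.tr * out.fs))
        untouched = np.ones(out.eeg_scalp.shape[1], bool)
        for e in (3, 9):
            untouched[e * spe:(e + 1) * spe] = False
        np.testing.assert_array_equal(out.eeg_scalp[:, untouched],
                                      fast_subject.eeg_scalp[:, untouched])
        assert ("eeg", 3) in out.truth.motion_epochs
        assert ("fmri", 9) in out.truth.motion_epochs

    def test_duplicate_epochs_rejected(self, fast_subject):
        with pytest.raises(ValueError):
            inject_motion(fast_subject, [2, 2])


class TestGenerateGroup:
    def test_subject_count_and_manifest(self, tmp_path, fast_config):
        import dataclasses

        cfg = dataclasses.replace(fast_config, n_subjects=3)
        manifest = generate_group(cfg, tmp_path / "g")
        dirs = sorted(p.name for p in (tmp_path / "g").iterdir() if p.is_dir())
        assert dirs == ["sub-01", "sub-02", "sub-03"]
        assert manifest["n_subjects"] == 3
        assert (tmp_path / "g" / "manifest.json").exists()

    def test_regeneration_is_byte_identical(self, tmp_path, fast_config):
        import dataclasses
        import hashlib

        cfg = dataclasses.replace(fast_config, n_subjects=2)
        generate_group(cfg, tmp_path / "a")
        generate_group(cfg, tmp_path / "b")
        for rel in sorted(p.relative_to(tmp_path / "a")
                          for p in (tmp_path / "a").rglob("*") if p.is_file()):
            ha = hashlib.sha256((tmp_path / "a" / rel).read_bytes()).hexdigest()
            hb = hashlib.sha256((tmp_path / "b" / rel).read_bytes()).hexdigest()
            assert ha == hb, rel

    def test_existing_dir_requires_overwrite(self, tmp_path, fast_config):
        import dataclasses

        cfg = dataclasses.replace(fast_config, n_subjects=1)
        generate_group(cfg, tmp_path / "g")
        with pytest.raises(FileExistsError):
            generate_group(cfg, tmp_path / "g")
        generate_group(cfg, tmp_path / "g", overwrite=True)

    def test_nine_subject_group(self, tmp_path, fast_config):
        # smallest real cohort size: nine volunteers
        import dataclasses

        cfg = dataclasses.replace(fast_config, n_subjects=9, duration_s=60.0)
        manifest = generate_group(cfg, tmp_path / "g9")
        assert len(manifest["subjects"]) == 9


class TestSubjectInvariants:
    def test_durations_agree_and_values_finite(self, fast_subject, fast_config):
        n_samp = fast_subject.eeg_scalp.shape[1]
        n_vol = fast_subject.rsn_bold.shape[1]
        assert abs(n_samp / fast_config.fs - n_vol * fast_config.tr) \
            <= fast_config.tr
        for arr in (fast_subject.eeg_scalp, fast_subject.eeg_source,
                    fast_subject.rsn_bold):
            assert np.all(np.isfinite(arr))

    def test_coupling_magnitude_bounded(self):
        with pytest.raises(ValueError):
            _truth(np.array([[1.5, 0, 0, 0, 0]]))

    def test_subject_regeneration_identical(self, fast_config):
        a = simulate_subject(fast_config, 55)
        b = simulate_subject(fast_config, 55)
        np.testing.assert_array_equal(a.eeg_scalp, b.eeg_scalp)
        np.testing.assert_array_equal(a.rsn_bold, b.rsn_bold)
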