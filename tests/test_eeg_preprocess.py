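"""EEG cleaning chain: filters, bad channels, splines, ASR, Laplacian,
band power, epoching."""

import warnings

import numpy as np
import pytest

from msfusion import eeg as eegmod
from msfusion import simulate as sim
from msfusion.containers import EegRecording, EventTable, MsfusionError
from msfusion.io import _fibonacci_hemisphere, template_positions
from msfusion.microstates import compute_gfp
from msfusion.splines import interpolate_field, surface_laplacian_operator


def _rec_from_sine(freq, fs=500.0, dur=20.0, n_ch=8):
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_ch, 1)) * np.linspace(1.0, 2.0, n_ch)[:, None]
    return EegRecording(data=data, fs=fs,
                        channel_names=[f"c{i}" for i in range(n_ch)],
                        channel_positions=_fibonacci_hemisphere(n_ch))


class TestFilterChain:
    @pytest.mark.parametrize("freq, check", [
        (0.1, lambda g: g < 0.05),          # below the 1 Hz high-pass
        (10.0, lambda g: 0.95 < g < 1.05),  # passband
        (60.0, lambda g: g < 10 ** (-30 / 20)),  # line frequency
    ])
    def test_frequency_response(self, freq, check):
        rec = _rec_from_sine(freq)
        out = eegmod.filter_chain(rec, line_freq=60.0)
        sl = slice(int(2 * out.fs), -int(2 * out.fs))  # skip filter edges
        gain = out.data[0, sl].std() / \
            (rec.data[0, int(4 * rec.fs):-int(4 * rec.fs)].std())
        assert check(gain)

    def test_downsamples_to_250(self):
        rec = _rec_from_sine(10.0)
        out = eegmod.filter_chain(rec)
        assert out.fs == 250.0
        assert out.n_samples == rec.n_samples // 2

    def test_low_rate_rejected(self):
        rec = _rec_from_sine(10.0, fs=400.0)
        with pytest.raises(MsfusionError):
            eegmod.filter_chain(rec, target_fs=250.0)


class TestBadChannels:
    def _clean_rec(self, protos6, seed=0):
        cfg = sim.SimConfig(trial_duration_s=40, n_trials=1, seed=seed)
        truth = sim.gen_state_sequence(cfg, seed, prototypes=protos6)
        eeg = sim.gen_eeg(truth, cfg, seed + 1)
        return eegmod.filter_chain(eeg)

    def test_clean_data_has_no_bads(self, protos6):
        rec = self._clean_rec(protos6)
        assert eegmod.detect_bad_channels(rec) == []

    def test_flat_channel_flagged(self, protos6):
        rec = self._clean_rec(protos6)
        rec.data[5] = 0.0
        assert rec.channel_names[5] in eegmod.detect_bad_channels(rec)

    def test_noise_channel_flagged(self, protos6):
        rec = self._clean_rec(protos6)
        rng = np.random.default_rng(1)
        rec.data[7] = rng.standard_normal(rec.n_samples) * rec.data[7].std()
        assert rec.channel_names[7] in eegmod.detect_bad_channels(rec)

    def test_exclusion_above_threshold(self, protos6):
        rec = self._clean_rec(protos6)
        rng = np.random.default_rng(2)
        for ch in range(6):
            rec.data[ch] = rng.standard_normal(rec.n_samples)
        report = eegmod.PreprocessReport()
        bads = eegmod.detect_bad_channels(rec, max_bad=5, report=report)
        assert len(bads) >= 6
        assert report.excluded


class TestSplineInterpolation:
    def test_constant_field_reproduced(self):
        pos = _fibonacci_hemisphere(64)
        field = np.full((60, 1), 7.5)
        est = interpolate_field(pos[:60], pos[60:], field)
        assert np.allclose(est, 7.5, atol=1e-6)

    def test_linear_field_on_dense_montage(self):
        """A field linear in position interpolates to < 2% RMS error."""
        pos = _fibonacci_hemisphere(128)
        w = np.array([1.0, -2.0, 0.5])
        field = (pos @ w)[:, None]
        take = np.arange(128) % 8 != 0  # remove every 8th electrode
        est = interpolate_field(pos[take], pos[~take], field[take])
        err = np.sqrt(np.mean((est - field[~take]) ** 2))
        assert err / field.std() < 0.02

    def test_good_channels_untouched(self, clean_eeg):
        rec, _ = clean_eeg
        out = eegmod.spherical_spline_interpolate(rec, [rec.channel_names[3]])
        others = [i for i in range(rec.n_channels) if i != 3]
        assert np.array_equal(out.data[others], rec.data[others])
        assert not np.array_equal(out.data[3], rec.data[3])


class TestRereference:
    def test_small_example(self):
        rec = EegRecording(data=np.array([[1.0], [2.0], [3.0]]), fs=1.0,
                           channel_names=list("abc"))
        out = eegmod.rereference_average(rec)
        assert np.allclose(out.data.ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent(self, clean_eeg):
        rec, _ = clean_eeg
        once = eegmod.rereference_average(rec)
        twice = eegmod.rereference_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_gfp_reference_invariant(self, small_session):
        _, _, eeg, _ = small_session
        shifted = eeg.copy_with(data=eeg.data + 42.0)
        g1 = compute_gfp(eeg).values
        g2 = compute_gfp(shifted).values
        assert np.allclose(g1, g2, atol=1e-9)


class TestAsr:
    def test_clean_data_nearly_untouched(self, clean_eeg):
        rec, _ = clean_eeg
        rec = eegmod.rereference_average(rec)
        out, report = eegmod.asr_clean(rec, k=20.0)
        assert report.fraction_samples_modified_by_asr < 0.01
        rel = np.linalg.norm(out.data - rec.data) / np.linalg.norm(rec.data)
        assert rel < 0.01

    def test_burst_removed(self, clean_eeg):
        rec, _ = clean_eeg
        rec = eegmod.rereference_average(rec)
        data = rec.data.copy()
        s = int(30.0 * rec.fs)
        e = s + int(0.2 * rec.fs)
        data[:3, s:e] += 500.0
        noisy = rec.copy_with(data=data)
        out, report = eegmod.asr_clean(noisy, k=20.0)
        burst_before = np.sqrt(np.mean((data[:3, s:e] - rec.data[:3, s:e]) ** 2))
        burst_after = np.sqrt(np.mean((out.data[:3, s:e] - rec.data[:3, s:e]) ** 2))
        assert burst_after < 0.2 * burst_before
        rest = np.ones(rec.n_samples, bool)
        rest[s - int(rec.fs):e + int(rec.fs)] = False
        rel = np.linalg.norm(out.data[:, rest] - rec.data[:, rest]) / \
            np.linalg.norm(rec.data[:, rest])
        assert rel < 0.01

    def test_infinite_k_is_identity(self, clean_eeg):
        rec, _ = clean_eeg
        out, report = eegmod.asr_clean(rec, k=np.inf)
        assert np.array_equal(out.data, rec.data)
        assert report.fraction_samples_modified_by_asr == 0.0

    def test_short_recording_rejected(self):
        rec = _rec_from_sine(10.0, dur=5.0)
        with pytest.raises(MsfusionError):
            eegmod.asr_clean(rec)


class TestSurfaceLaplacian:
    def test_constant_map_maps_to_zero(self):
        pos = _fibonacci_hemisphere(32)
        L = surface_laplacian_operator(pos)
        out = L @ np.full(32, 5.0)
        assert np.abs(out).max() < 1e-6 * 5.0

    def test_linearity(self, clean_eeg):
        rec, _ = clean_eeg
        x = rec.data[:, :100]
        y = rec.data[:, 100:200]
        L = surface_laplacian_operator(rec.channel_positions)
        assert np.allclose(L @ (2.0 * x + 3.0 * y),
                           2.0 * (L @ x) + 3.0 * (L @ y), atol=1e-10)

    def test_spherical_harmonic_eigenvalue(self):
        """On a dense full-sphere montage, the spline Laplacian of a
        degree-2 spherical harmonic is -l(l+1)/r^2 times the harmonic."""
        i = np.arange(400)
        z = -1 + 2 * (i + 0.5) / 400
        phi = i * np.pi * (3 - np.sqrt(5))
        r = np.sqrt(1 - z ** 2)
        pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        radius = 0.085
        harm = pos[:, 0] * pos[:, 1]  # degree-2 harmonic xy
        L = surface_laplacian_operator(pos, head_radius_m=radius)
        out = L @ harm
        expected = -6.0 / radius ** 2 * harm
        err = np.linalg.norm(out - expected) / np.linalg.norm(expected)
        assert err < 0.05

    def test_low_channel_count_warns(self):
        rec = _rec_from_sine(10.0, n_ch=8)
        with pytest.warns(UserWarning, match="Laplacian"):
            eegmod.surface_laplacian(rec)


class TestBandpower:
    def test_sinusoid_power(self):
        rec = _rec_from_sine(10.0, n_ch=1, dur=30.0)
        env = eegmod.bandpower_envelope(rec, out_fs=5.0)
        inner = env[0, 10:-10]
        assert np.allclose(inner, 0.5, rtol=0.05)

    def test_quadratic_scaling(self):
        rec = _rec_from_sine(10.0, n_ch=1, dur=30.0)
        scaled = rec.copy_with(data=3.0 * rec.data)
        e1 = eegmod.bandpower_envelope(rec, out_fs=5.0)
        e2 = eegmod.bandpower_envelope(scaled, out_fs=5.0)
        assert np.allclose(e2, 9.0 * e1, rtol=1e-6)

    def test_out_of_band_rejected(self):
        in_band = _rec_from_sine(10.0, n_ch=1, dur=30.0, fs=250.0)
        out_band = _rec_from_sine(80.0, n_ch=1, dur=30.0, fs=250.0)
        e_in = eegmod.bandpower_envelope(in_band, out_fs=5.0)[0, 10:-10]
        e_out = eegmod.bandpower_envelope(out_band, out_fs=5.0)[0, 10:-10]
        assert e_out.mean() < 0.05 * e_in.mean()

    def test_band_above_nyquist_rejected(self):
        rec = _rec_from_sine(10.0, fs=60.0)
        with pytest.raises(MsfusionError):
            eegmod.bandpower_envelope(rec, low=1.0, high=40.0)


class TestEpochExtract:
    def _rec_with_events(self, onsets, labels, dur=120.0, fs=250.0):
        rng = np.random.default_rng(0)
        ev = EventTable.from_arrays(onsets, np.zeros(len(onsets)), labels)
        return EegRecording(data=rng.standard_normal((4, int(dur * fs))),
                            fs=fs, channel_names=list("abcd")), ev

    def test_sample_arithmetic(self):
        rec, ev = self._rec_with_events([100.0], ["task_start"])
        eps = eegmod.epoch_extract(rec, ev, "task_start", length_s=10.0)
        assert len(eps) == 1
        assert eps[0].shape == (4, 2500)
        assert np.array_equal(eps[0], rec.data[:, 25000:27500])

    def test_partial_epoch_dropped(self):
        rec, ev = self._rec_with_events([116.0], ["needle_drop"])
        with pytest.warns(UserWarning, match="partial"):
            eps = eegmod.epoch_extract(rec, ev, "error", length_s=10.0)
        assert eps == []

    def test_overlapping_epochs_both_emitted(self):
        rec, ev = self._rec_with_events(
            [50.0, 55.0], ["needle_drop", "incorrect_insertion"])
        eps = eegmod.epoch_extract(rec, ev, "error", length_s=10.0)
        assert len(eps) == 2

    def test_no_events_warns_empty(self):
        rec, ev = self._rec_with_events([10.0], ["task_start"])
        with pytest.warns(UserWarning, match="no events"):
            assert eegmod.epoch_extract(rec, ev, "error") == []
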