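import numpy as np
import pytest

from bleatkit.audio_io import FrameSpec, Waveform
from bleatkit.spectral import (
    Spectrogram,
    spectral_shape_features,
    stft,
    temporal_energy_features,
    time_evolution_features,
)
from tests.conftest import RATE, make_sine


def make_spectrogram(mags: np.ndarray, rate: int = RATE, spec: FrameSpec | None = None) -> Spectrogram:
    n_frames, n_bins = mags.shape
    n_fft = 2 * (n_bins - 1)
    hop = min(spec.hop_length if spec else 512, n_fft)
    return Spectrogram(
        magnitudes=mags,
        bin_freqs=np.fft.rfftfreq(n_fft, 1 / rate),
        frame_times=hop * np.arange(n_frames) / rate,
        rate=rate,
        spec=FrameSpec(frame_length=n_fft, hop_length=hop),
    )


class TestStft:
    def test_frame_count_matches_reference_loop(self, sine_440, frame_spec):
        S = stft(sine_440, frame_spec)
        # reference: one frame per hop over the center-padded signal
        n = 0
        center = 0
        while center <= len(sine_440):
            n += 1
            center += frame_spec.hop_length
        assert S.n_frames == n == 87
        assert S.n_bins == frame_spec.frame_length // 2 + 1

    def test_zero_waveform_zero_magnitudes(self, silence):
        S = stft(silence)
        assert not S.magnitudes.any()

    def test_pure_tone_argmax_bin(self, frame_spec):
        w = make_sine(1000.0)
        S = stft(w, frame_spec)
        expected_bin = int(np.argmin(np.abs(S.bin_freqs - 1000.0)))
        interior = S.magnitudes[2:-2]
        assert np.all(np.argmax(interior, axis=1) == expected_bin)

    def test_short_signal_single_frame(self):
        w = Waveform(samples=np.ones(100) * 0.1, rate=RATE)
        S = stft(w)
        assert S.n_frames == 1

    def test_zero_hop_rejected(self):
        with pytest.raises(ValueError):
            FrameSpec(frame_length=2048, hop_length=0)


class TestTemporalEnergy:
    def test_constant_signal(self):
        w = Waveform(samples=np.full(2 * RATE, 0.5), rate=RATE)
        f = temporal_energy_features(w)
        assert f["rms_mean"] == pytest.approx(0.5)
        assert f["rms_std"] == pytest.approx(0.0, abs=1e-12)
        assert f["zcr_mean"] == 0.0

    def test_alternating_signal_zcr_one(self):
        w = Waveform(samples=np.tile([1.0, -1.0], RATE), rate=RATE)
        f = temporal_energy_features(w)
        assert f["zcr_mean"] == pytest.approx(1.0)

    def test_sine_zcr_and_rms_closed_form(self, sine_440):
        # brute-force oracle: count sign changes over the whole signal
        x = sine_440.samples
        brute_zcr = np.mean(np.signbit(x[1:]) != np.signbit(x[:-1]))
        f = temporal_energy_features(sine_440)
        assert f["zcr_mean"] == pytest.approx(brute_zcr, abs=2e-3)
        assert f["zcr_mean"] == pytest.approx(2 * 440 / RATE, rel=0.02)
        assert f["rms_mean"] == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_autocorr_peak_high_for_periodic_low_for_noise(self, sine_220, white_noise, silence):
        assert temporal_energy_features(sine_220)["autocorr_peak"] > 0.9
        assert temporal_energy_features(white_noise)["autocorr_peak"] < 0.3
        assert temporal_energy_features(silence)["autocorr_peak"] == 0.0

    def test_zcr_bounds(self, white_noise):
        f = temporal_energy_features(white_noise)
        assert 0.0 <= f["zcr_mean"] <= 1.0


class TestTimeEvolution:
    def test_identical_frames_zero_flux(self):
        mags = np.tile(np.random.default_rng(0).uniform(0, 1, 1025), (10, 1))
        f = time_evolution_features(make_spectrogram(mags))
        assert f["flux_mean"] == 0.0
        assert f["flux_std"] == 0.0

    def test_single_energetic_frame_centroid(self):
        mags = np.zeros((20, 1025))
        mags[7, 100] = 3.0
        S = make_spectrogram(mags)
        f = time_evolution_features(S)
        assert f["temporal_centroid"] == pytest.approx(S.frame_times[7])

    def test_uniform_envelope_centroid_midpoint(self):
        mags = np.ones((87, 1025))
        S = make_spectrogram(mags)
        f = time_evolution_features(S)
        midpoint = S.frame_times[-1] / 2
        assert f["temporal_centroid"] == pytest.approx(midpoint, rel=1e-9)

    def test_silent_input_centroid_midpoint(self):
        mags = np.zeros((21, 1025))
        S = make_spectrogram(mags)
        f = time_evolution_features(S)
        assert f["temporal_centroid"] == pytest.approx(S.frame_times[-1] / 2)

    def test_flux_matches_brute_force(self):
        rng = np.random.default_rng(3)
        mags = rng.uniform(0, 1, (12, 33))
        S = make_spectrogram(mags)
        f = time_evolution_features(S)
        flux = [0.0] + [np.mean(np.maximum(mags[t] - mags[t - 1], 0)) for t in range(1, 12)]
        assert f["flux_mean"] == pytest.approx(np.mean(flux), rel=1e-12)
        assert f["flux_std"] == pytest.approx(np.std(flux), rel=1e-12)


class TestSpectralShape:
    def test_single_bin_spectrum(self):
        mags = np.zeros((5, 1025))
        mags[:, 200] = 2.0
        S = make_spectrogram(mags)
        f = spectral_shape_features(S)
        freq = S.bin_freqs[200]
        assert f["centroid_mean"] == pytest.approx(freq)
        assert f["bandwidth_mean"] == pytest.approx(0.0, abs=1e-9)
        assert f["flatness"] == pytest.approx(0.0, abs=1e-6)
        assert f["entropy"] == pytest.approx(0.0, abs=1e-9)

    def test_two_equal_bins(self):
        mags = np.zeros((3, 1025))
        mags[:, 100] = 1.0
        mags[:, 300] = 1.0
        S = make_spectrogram(mags)
        f = spectral_shape_features(S)
        assert f["centroid_mean"] == pytest.approx((S.bin_freqs[100] + S.bin_freqs[300]) / 2)
        assert f["entropy"] == pytest.approx(1.0)

    def test_flat_spectrum(self):
        mags = np.ones((4, 1025))
        S = make_spectrogram(mags)
        f = spectral_shape_features(S)
        assert f["flatness"] == pytest.approx(1.0, rel=1e-9)
        assert f["entropy"] == pytest.approx(np.log2(1025), rel=1e-9)

    def test_brute_force_reference_on_random_input(self):
        # independent per-frame loops over the DFT
        rng = np.random.default_rng(7)
        w = Waveform(samples=rng.uniform(-0.5, 0.5, int(0.2 * RATE)), rate=RATE)
        spec = FrameSpec()
        S = stft(w, spec)
        f = spectral_shape_features(S)
        cents, bws, rolls, ents, flats = [], [], [], [], []
        for t in range(S.n_frames):
            m = S.magnitudes[t]
            total = m.sum()
            c = (S.bin_freqs * m).sum() / total
            cents.append(c)
            bws.append(np.sqrt(((S.bin_freqs - c) ** 2 * m).sum() / total))
            rolls.append(S.bin_freqs[np.searchsorted(np.cumsum(m), 0.85 * total)])
            p = m**2
            pn = p / p.sum()
            ents.append(-np.sum(pn[pn > 0] * np.log2(pn[pn > 0])))
            flats.append(np.exp(np.mean(np.log(np.maximum(p, 1e-12)))) / np.mean(p))
        assert f["centroid_mean"] == pytest.approx(np.mean(cents), rel=1e-6)
        assert f["bandwidth_mean"] == pytest.approx(np.mean(bws), rel=1e-6)
        assert f["rolloff_mean"] == pytest.approx(np.mean(rolls), rel=1e-6)
        assert f["entropy"] == pytest.approx(np.mean(ents), rel=1e-6)
        assert f["flatness"] == pytest.approx(np.mean(flats), rel=1e-6)

    def test_rolloff_below_nyquist_and_bandwidth_nonnegative(self, white_noise):
        f = spectral_shape_features(stft(white_noise))
        assert f["rolloff_mean"] <= RATE / 2
        assert f["bandwidth_mean"] >= 0

    @pytest.mark.parametrize("scale", [0.1, 3.0])
    def test_amplitude_scaling_invariance(self, scale):
        rng = np.random.default_rng(11)
        x = rng.uniform(-0.2, 0.2, int(0.5 * RATE))
        f1 = spectral_shape_features(stft(Waveform(samples=x, rate=RATE)))
        f2 = spectral_shape_features(stft(Waveform(samples=scale * x, rate=RATE)))
        for key in ("centroid_mean", "rolloff_mean", "flatness", "entropy", "contrast_mean_3"):
            assert f2[key] == pytest.approx(f1[key], rel=1e-6), key
        t1 = temporal_energy_features(Waveform(samples=x, rate=RATE))
        t2 = temporal_energy_features(Waveform(samples=scale * x, rate=RATE))
        assert t2["zcr_mean"] == t1["zcr_mean"]
        assert t2["rms_mean"] == pytest.approx(scale * t1["rms_mean"], rel=1e-9)

    def test_contrast_count_and_tonal_vs_noise(self, sine_220, white_noise):
        f_tone = spectral_shape_features(stft(sine_220))
        f_noise = spectral_shape_features(stft(white_noise))
        # tonal signal has a sharper peak/valley structure in its F0 band
        assert f_tone["contrast_mean_1"] > f_noise["contrast_mean_1"]
        assert len([k for k in f_tone if k.startswith("contrast_")]) == 14
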