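"""STFT plus the temporal/energy, time-evolution, and spectral-shape descriptors.

Temporal descriptors (RMS, ZCR, autocorrelation peak) are computed on
non-centered frames of the raw signal so a constant input yields constant
per-frame statistics; all spectral descriptors run on the center-padded
magnitude spectrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from bleatkit.audio_io import FrameSpec, Waveform

logger = logging.getLogger(__name__)

_EPS = 1e-12
CONTRAST_FMIN = 200.0
CONTRAST_N_BANDS = 7
CONTRAST_QUANTILE = 0.02
ROLLOFF_FRACTION = 0.85
AUTOCORR_FMIN = 50.0
AUTOCORR_FMAX = 1000.0


@dataclass(frozen=True)
class Spectrogram:
    """Frames x bins magnitude matrix with its frequency/time axes."""

    magnitudes: np.ndarray  # (n_frames, n_bins), non-negative
    bin_freqs: np.ndarray  # (n_bins,) Hz
    frame_times: np.ndarray  # (n_frames,) seconds
    rate: int
    spec: FrameSpec

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=np.float64)
        if m.ndim != 2:
            raise ValueError("magnitudes must be 2-D (frames x bins)")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("magnitudes must be finite and non-negative")
        object.__setattr__(self, "magnitudes", m)
        object.__setattr__(self, "bin_freqs", np.asarray(self.bin_freqs, dtype=np.float64))
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, dtype=np.float64))

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[1]


def _frame_signal(x: np.ndarray, frame_length: int, hop_length: int) -> np.ndarray:
    """Non-centered framing: frames x frame_length view (copy) of x."""
    if len(x) < frame_length:
        out = np.zeros((1, frame_length))
        out[0, : len(x)] = x
        return out
    n_frames = 1 + (len(x) - frame_length) // hop_length
    idx = np.arange(frame_length)[None, :] + hop_length * np.arange(n_frames)[:, None]
    return x[idx]


def stft(w: Waveform, spec: FrameSpec | None = None) -> Spectrogram:
    """Hann-windowed magnitude STFT with center padding.

    Frame count is ``1 + len(w) // hop``; frames are centered on
    ``t = i * hop / rate``.
    """
    if spec is None:
        spec = FrameSpec()
    if len(w) == 0:
        raise ValueError("cannot compute STFT of an empty waveform")
    fl, hop = spec.frame_length, spec.hop_length
    pad = fl // 2
    x = np.pad(w.samples, (pad, pad))
    n_frames = 1 + len(w) // hop
    idx = np.arange(fl)[None, :] + hop * np.arange(n_frames)[:, None]
    # guard: the final centered frame may poke past the padded end
    extra = int(idx.max()) + 1 - len(x)
    if extra > 0:
        x = np.pad(x, (0, extra))
    frames = x[idx]
    window = get_window(spec.window, fl, fftbins=True)
    mags = np.abs(np.fft.rfft(frames * window, axis=1))
    bin_freqs = np.fft.rfftfreq(fl, d=1.0 / w.rate)
    frame_times = hop * np.arange(n_frames) / w.rate
    return Spectrogram(magnitudes=mags, bin_freqs=bin_freqs, frame_times=frame_times, rate=w.rate, spec=spec)


def temporal_energy_features(w: Waveform, spec: FrameSpec | None = None) -> dict[str, float]:
    """RMS and ZCR frame statistics plus the normalized autocorrelation peak.

    ZCR is the fraction of adjacent-sample pairs within a frame whose sign
    changes; the autocorrelation peak is searched over lags corresponding to
    50-1000 Hz so lag 0 never wins.
    """
    if spec is None:
        spec = FrameSpec()
    x = w.samples
    frames = _frame_signal(x, spec.frame_length, spec.hop_length)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    signs = np.signbit(frames)
    zcr = np.mean(signs[:, 1:] != signs[:, :-1], axis=1)

    # biased autocorrelation, normalized at lag 0
    n = len(x)
    energy = float(np.dot(x, x))
    if energy <= _EPS:
        ac_peak = 0.0
    else:
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        spec_x = np.fft.rfft(x, nfft)
        ac = np.fft.irfft(spec_x * np.conj(spec_x), nfft)[:n] / energy
        lag_min = max(1, int(np.floor(w.rate / AUTOCORR_FMAX)))
        lag_max = min(n - 1, int(np.ceil(w.rate / AUTOCORR_FMIN)))
        ac_peak = float(np.max(ac[lag_min : lag_max + 1])) if lag_max >= lag_min else 0.0

    return {
        "rms_mean": float(np.mean(rms)),
        "rms_std": float(np.std(rms)),
        "zcr_mean": float(np.mean(zcr)),
        "zcr_std": float(np.std(zcr)),
        "autocorr_peak": ac_peak,
    }


def time_evolution_features(S: Spectrogram) -> dict[str, float]:
    """Spectral flux statistics and the temporal centroid of the energy envelope.

    Flux is the per-frame-pair mean (over bins) of half-wave-rectified
    magnitude increase; the first frame has flux 0.  The temporal centroid is
    the energy-weighted mean frame time; silence falls back to the midpoint.
    """
    m = S.magnitudes
    flux = np.zeros(S.n_frames)
    if S.n_frames > 1:
        diff = m[1:] - m[:-1]
        flux[1:] = np.mean(np.maximum(diff, 0.0), axis=1)
    envelope = np.sqrt(np.mean(m**2, axis=1))
    total = float(envelope.sum())
    if total <= _EPS:
        logger.warning("time_evolution_features: silent input, centroid set to midpoint")
        centroid = float(S.frame_times[-1]) / 2.0 if S.n_frames > 1 else 0.0
    else:
        centroid = float(np.dot(S.frame_times, envelope) / total)
    return {
        "flux_mean": float(np.mean(flux)),
        "flux_std": float(np.std(flux)),
        "temporal_centroid": centroid,
    }


def _contrast_band_edges(rate: float) -> np.ndarray:
    """Octave-spaced band edges from 200 Hz: [0, 200, 400, ..., Nyquist]."""
    edges = [0.0] + [CONTRAST_FMIN * 2.0**k for k in range(CONTRAST_N_BANDS - 1)]
    edges.append(rate / 2.0)
    return np.asarray(edges)


def spectral_contrast(S: Spectrogram) -> np.ndarray:
    """Per-frame peak-valley log-power contrast in 7 octave bands (frames x 7)."""
    power = S.magnitudes**2
    edges = _contrast_band_edges(S.rate)
    out = np.zeros((S.n_frames, CONTRAST_N_BANDS))
    for b in range(CONTRAST_N_BANDS):
        lo, hi = edges[b], edges[b + 1]
        if b == CONTRAST_N_BANDS - 1:
            mask = (S.bin_freqs >= lo) & (S.bin_freqs <= hi)
        else:
            mask = (S.bin_freqs >= lo) & (S.bin_freqs < hi)
        band = power[:, mask]
        if band.shape[1] == 0:
            continue
        band_db = 10.0 * np.log10(np.maximum(band, _EPS))
        band_db = np.sort(band_db, axis=1)
        k = max(1, int(round(CONTRAST_QUANTILE * band.shape[1])))
        valley = band_db[:, :k].mean(axis=1)
        peak = band_db[:, -k:].mean(axis=1)
        out[:, b] = peak - valley
    return out


def spectral_shape_features(S: Spectrogram) -> dict[str, float]:
    """Centroid/bandwidth/roll-off stats, 7-band contrast stats, flatness, entropy.

    Silent frames contribute 0 to centroid, bandwidth and roll-off (0/0
    guard).  Flatness and entropy are clip-level frame means.
    """
    m = S.magnitudes
    f = S.bin_freqs
    mag_sum = m.sum(axis=1)
    safe = np.where(mag_sum > _EPS, mag_sum, 1.0)
    nonsilent = mag_sum > _EPS

    centroid = np.where(nonsilent, m @ f / safe, 0.0)
    spread = np.sqrt(np.maximum((m * (f[None, :] - centroid[:, None]) ** 2).sum(axis=1) / safe, 0.0))
    bandwidth = np.where(nonsilent, spread, 0.0)

    cum = np.cumsum(m, axis=1)
    target = ROLLOFF_FRACTION * mag_sum
    roll_idx = np.argmax(cum >= target[:, None], axis=1)
    rolloff = np.where(nonsilent, f[roll_idx], 0.0)

    power = m**2
    p_sum = power.sum(axis=1)
    p_safe = np.where(p_sum > _EPS, p_sum, 1.0)
    # geometric / arithmetic mean ratio of the power spectrum
    log_gm = np.mean(np.log(np.maximum(power, _EPS)), axis=1)
    am = p_sum / S.n_bins
    flatness = np.where(p_sum > _EPS, np.exp(log_gm) / np.where(am > _EPS, am, 1.0), 0.0)
    flatness = np.clip(flatness, 0.0, 1.0)

    p_norm = power / p_safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_terms = np.where(p_norm > 0, -p_norm * np.log2(p_norm), 0.0)
    entropy = np.where(p_sum > _EPS, ent_terms.sum(axis=1), 0.0)

    contrast = spectral_contrast(S)
    out: dict[str, float] = {
        "centroid_mean": float(np.mean(centroid)),
        "centroid_std": float(np.std(centroid)),
        "bandwidth_mean": float(np.mean(bandwidth)),
        "bandwidth_std": float(np.std(bandwidth)),
        "rolloff_mean": float(np.mean(rolloff)),
        "rolloff_std": float(np.std(rolloff)),
    }
    for b in range(CONTRAST_N_BANDS):
        out[f"contrast_mean_{b}"] = float(np.mean(contrast[:, b]))
    for b in range(CONTRAST_N_BANDS):
        out[f"contrast_std_{b}"] = float(np.std(contrast[:, b]))
    out["flatness"] = float(np.mean(flatness))
    out["entropy"] = float(np.mean(entropy))
    return out
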