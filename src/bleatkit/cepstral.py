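"""Mel-frequency cepstral coefficients, their temporal derivatives, and stats.

Mel bank: 128 triangular filters spanning 0 Hz to Nyquist with Slaney-style
area normalization; coefficients come from an orthonormal DCT-II of the
dB-scaled mel power spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.fft import dct

from bleatkit.spectral import Spectrogram

N_MELS = 128
_LOG_FLOOR = 1e-10
_DELTA_HALF_WIDTH = 4  # 9-frame regression window


@dataclass(frozen=True)
class CepstralMatrix:
    """Frames x n_coeff cepstral coefficients at derivative order 0, 1, or 2."""

    values: np.ndarray
    n_coeff: int
    order: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != self.n_coeff:
            raise ValueError(f"values must be (frames, {self.n_coeff}), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("cepstral matrix contains non-finite entries")
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1, or 2")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    f = np.asarray(f, dtype=np.float64)
    f_sp = 200.0 / 3
    mel = f / f_sp
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    log_region = f >= min_log_hz
    mel = np.where(log_region, min_log_mel + np.log(np.maximum(f, min_log_hz) / min_log_hz) / logstep, mel)
    return mel


def _mel_to_hz(mel: np.ndarray) -> np.ndarray:
    mel = np.asarray(mel, dtype=np.float64)
    f_sp = 200.0 / 3
    freq = mel * f_sp
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    log_region = mel >= min_log_mel
    freq = np.where(log_region, min_log_hz * np.exp(logstep * (mel - min_log_mel)), freq)
    return freq


@lru_cache(maxsize=8)
def _mel_bank(rate: int, n_fft: int, n_mels: int = N_MELS) -> np.ndarray:
    """Triangular Slaney-normalized mel filter bank, shape (n_mels, n_bins)."""
    fmax = rate / 2.0
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bank = np.zeros((n_mels, len(bin_freqs)))
    for i in range(n_mels):
        lower, center, upper = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - lower) / max(center - lower, 1e-12)
        down = (upper - bin_freqs) / max(upper - center, 1e-12)
        bank[i] = np.maximum(0.0, np.minimum(up, down))
        # Slaney: normalize each filter to unit area (2 / bandwidth)
        bank[i] *= 2.0 / (upper - lower)
    return bank


def mfcc(S: Spectrogram, n_coeff: int = 40) -> CepstralMatrix:
    """MFCCs from the 128-band log-mel power spectrum of ``S``.

    Coefficients are the first ``n_coeff`` outputs of an orthonormal DCT-II
    across mel bands, per frame.
    """
    if n_coeff < 1 or n_coeff > N_MELS:
        raise ValueError(f"n_coeff must be in [1, {N_MELS}], got {n_coeff}")
    bank = _mel_bank(S.rate, S.spec.frame_length)
    mel_power = S.magnitudes**2 @ bank.T
    log_mel = 10.0 * np.log10(np.maximum(mel_power, _LOG_FLOOR))
    coeffs = dct(log_mel, type=2, axis=1, norm="ortho")[:, :n_coeff]
    return CepstralMatrix(values=coeffs, n_coeff=n_coeff, order=0)


def delta(C: CepstralMatrix, order: int = 1) -> CepstralMatrix:
    """Local linear-regression slope over a 9-frame window (edge-replicated).

    ``order=2`` is the delta of the delta.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if order == 2:
        return CepstralMatrix(values=delta(delta(C, 1), 1).values, n_coeff=C.n_coeff, order=2)
    n = _DELTA_HALF_WIDTH
    v = C.values
    padded = np.pad(v, ((n, n), (0, 0)), mode="edge")
    num = np.zeros_like(v)
    for k in range(1, n + 1):
        num += k * (padded[n + k : n + k + len(v)] - padded[n - k : n - k + len(v)])
    denom = 2.0 * sum(k * k for k in range(1, n + 1))
    return CepstralMatrix(values=num / denom, n_coeff=C.n_coeff, order=min(C.order + 1, 2))


def cepstral_stats(C: CepstralMatrix, which: str = "mean", prefix: str = "mfcc") -> dict[str, float]:
    """Across-frame mean (and optionally population std) per coefficient.

    Names follow the ``<prefix>_mean_<i>`` / ``<prefix>_std_<i>`` convention
    with 0-based coefficient indices.
    """
    if which not in ("mean", "mean_and_std"):
        raise ValueError(f"which must be 'mean' or 'mean_and_std', got {which!r}")
    means = C.values.mean(axis=0)
    out = {f"{prefix}_mean_{i}": float(means[i]) for i in range(C.n_coeff)}
    if which == "mean_and_std":
        stds = C.values.std(axis=0)  # population std, ddof=0
        out.update({f"{prefix}_std_{i}": float(stds[i]) for i in range(C.n_coeff)})
    return out
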