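"""Fundamental-frequency tracking (probabilistic YIN) and ecoacoustic indices.

The tracker follows the pYIN recipe: per-frame YIN difference function,
cumulative-mean-normalized, local minima turned into F0 candidates whose
probabilities come from a beta prior over YIN thresholds, then Viterbi
decoding over discretized pitch states with explicit voiced/unvoiced pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import beta as beta_dist

from bleatkit.audio_io import FrameSpec, Waveform
from bleatkit.spectral import Spectrogram

logger = logging.getLogger(__name__)

DEFAULT_FMIN = 65.0
DEFAULT_FMAX = 2093.0
_N_THRESHOLDS = 100
_BETA_A, _BETA_B = 2.0, 18.0
_NO_TROUGH_PROB = 0.01
_BINS_PER_SEMITONE = 5
_MAX_JUMP_BINS = 12
_SWITCH_PROB = 0.01
_EPS = 1e-12


@dataclass(frozen=True)
class PitchTrack:
    """Per-frame F0 (Hz, meaningful only where voiced) with voicing flags."""

    f0: np.ndarray
    voiced: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        f0 = np.asarray(self.f0, dtype=np.float64)
        voiced = np.asarray(self.voiced, dtype=bool)
        times = np.asarray(self.frame_times, dtype=np.float64)
        if not (len(f0) == len(voiced) == len(times)):
            raise ValueError("f0, voiced, frame_times lengths disagree")
        object.__setattr__(self, "f0", f0)
        object.__setattr__(self, "voiced", voiced)
        object.__setattr__(self, "frame_times", times)

    @property
    def n_frames(self) -> int:
        return len(self.f0)

    @property
    def voiced_fraction(self) -> float:
        return float(np.mean(self.voiced)) if self.n_frames else 0.0


def _difference_function(frames: np.ndarray, window: int, tau_max: int) -> np.ndarray:
    """YIN difference d(tau) = sum_{j<W} (x_j - x_{j+tau})^2, vectorized over frames."""
    n_frames, frame_length = frames.shape
    nfft = int(2 ** np.ceil(np.log2(frame_length + window)))
    fx = np.fft.rfft(frames, nfft, axis=1)
    fw = np.fft.rfft(frames[:, :window], nfft, axis=1)
    corr = np.fft.irfft(fx * np.conj(fw), nfft, axis=1)[:, : tau_max + 1]
    sq = frames**2
    cum = np.concatenate([np.zeros((n_frames, 1)), np.cumsum(sq, axis=1)], axis=1)
    e0 = cum[:, window]  # sum of x_j^2, j < W
    taus = np.arange(tau_max + 1)
    e_tau = cum[:, taus + window] - cum[:, taus]  # sum of x_{j+tau}^2
    d = e0[:, None] + e_tau - 2.0 * corr
    return np.maximum(d, 0.0)


def _cmnd(d: np.ndarray) -> np.ndarray:
    """Cumulative-mean-normalized difference; defined as 1 where the running sum is 0."""
    taus = np.arange(1, d.shape[1])
    running = np.cumsum(d[:, 1:], axis=1)
    out = np.ones_like(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = d[:, 1:] * taus[None, :] / running
    out[:, 1:] = np.where(running > _EPS, ratio, 1.0)
    return out


def _parabolic_refine(cmnd_row: np.ndarray, tau: int) -> tuple[float, float]:
    """Parabolic interpolation of a local minimum: refined (tau, value)."""
    if tau <= 0 or tau >= len(cmnd_row) - 1:
        return float(tau), float(cmnd_row[tau])
    a, b, c = cmnd_row[tau - 1], cmnd_row[tau], cmnd_row[tau + 1]
    denom = a - 2 * b + c
    if denom <= _EPS:
        return float(tau), float(b)
    shift = 0.5 * (a - c) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    value = b - 0.25 * (a - c) * shift
    return tau + shift, float(value)


def _threshold_prior() -> tuple[np.ndarray, np.ndarray]:
    """Discretized Beta(2, 18) prior mass over YIN thresholds in (0, 1]."""
    edges = np.linspace(0.0, 1.0, _N_THRESHOLDS + 1)
    mass = np.diff(beta_dist.cdf(edges, _BETA_A, _BETA_B))
    return edges[1:], mass


def pyin_track(
    w: Waveform,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    spec: FrameSpec | None = None,
) -> PitchTrack:
    """Probabilistic YIN pitch track with voiced/unvoiced Viterbi smoothing."""
    if spec is None:
        spec = FrameSpec()
    nyquist = w.rate / 2.0
    if not (0 < fmin < fmax < nyquist):
        raise ValueError(f"need 0 < fmin < fmax < Nyquist, got ({fmin}, {fmax}) at rate {w.rate}")
    fl, hop = spec.frame_length, spec.hop_length
    if len(w) < fl:
        return PitchTrack(f0=np.zeros(0), voiced=np.zeros(0, bool), frame_times=np.zeros(0))

    window = fl // 2
    tau_min = max(1, int(np.floor(w.rate / fmax)))
    tau_max = min(window - 1, int(np.ceil(w.rate / fmin)))

    pad = fl // 2
    x = np.pad(w.samples, (pad, pad))
    n_frames = 1 + len(w) // hop
    idx = np.arange(fl)[None, :] + hop * np.arange(n_frames)[:, None]
    extra = int(idx.max()) + 1 - len(x)
    if extra > 0:
        x = np.pad(x, (0, extra))
    frames = x[idx]
    frame_times = hop * np.arange(n_frames) / w.rate

    d = _difference_function(frames, window, tau_max)
    cm = _cmnd(d)

    thresholds, prior_mass = _threshold_prior()

    # pitch state grid (log-spaced)
    n_bins = int(np.ceil(12 * np.log2(fmax / fmin) * _BINS_PER_SEMITONE)) + 1
    bin_freqs = fmin * 2.0 ** (np.arange(n_bins) / (12.0 * _BINS_PER_SEMITONE))

    obs_v = np.zeros((n_frames, n_bins))
    cand_freqs: list[list[float]] = []
    for t in range(n_frames):
        row = cm[t]
        interior = row[tau_min + 1 : tau_max]
        is_min = (interior < row[tau_min : tau_max - 1]) & (interior <= row[tau_min + 2 : tau_max + 1])
        trough_taus = np.nonzero(is_min)[0] + tau_min + 1
        freqs: list[float] = []
        if len(trough_taus) > 0:
            refined = [_parabolic_refine(row, int(tau)) for tau in trough_taus]
            vals = np.array([v for _, v in refined])
            probs = np.zeros(len(refined))
            # each threshold's prior mass goes to the first trough below it
            below = vals[None, :] < thresholds[:, None]  # (thresholds, troughs)
            any_below = below.any(axis=1)
            first = np.argmax(below, axis=1)
            np.add.at(probs, first[any_below], prior_mass[any_below])
            if not any_below.all():
                probs[int(np.argmin(vals))] += _NO_TROUGH_PROB * prior_mass[~any_below].sum()
            for (tau_ref, _), p in zip(refined, probs):
                if p <= 0:
                    continue
                f0 = w.rate / tau_ref
                if not (fmin <= f0 <= fmax):
                    continue
                b = int(round(12 * _BINS_PER_SEMITONE * np.log2(f0 / fmin)))
                if 0 <= b < n_bins:
                    obs_v[t, b] += p
                    freqs.append(f0)
        cand_freqs.append(freqs)

    voiced_prob = obs_v.sum(axis=1)
    obs_u = np.maximum(1.0 - voiced_prob, 1e-6)[:, None] / n_bins * np.ones((1, n_bins))

    states = _viterbi(np.log(obs_v + 1e-30), np.log(obs_u))

    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    for t in range(n_frames):
        s = states[t]
        if s < n_bins and obs_v[t].sum() > 0:
            voiced[t] = True
            center = bin_freqs[s]
            if cand_freqs[t]:
                f0[t] = min(cand_freqs[t], key=lambda f: abs(np.log(f / center)))
            else:
                f0[t] = center
    return PitchTrack(f0=f0, voiced=voiced, frame_times=frame_times)


def _viterbi(log_obs_v: np.ndarray, log_obs_u: np.ndarray) -> np.ndarray:
    """Viterbi over paired voiced/unvoiced pitch bins with banded transitions.

    States 0..n_bins-1 are voiced, n_bins..2n_bins-1 unvoiced.  Within a
    voicing state the pitch may move at most ``_MAX_JUMP_BINS`` bins per
    frame; voicing flips stay on the same bin with probability
    ``_SWITCH_PROB``.
    """
    n_frames, n_bins = log_obs_v.shape
    log_stay = np.log1p(-_SWITCH_PROB)
    log_switch = np.log(_SWITCH_PROB)
    width = 2 * _MAX_JUMP_BINS + 1

    def windowed_max(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        padded = np.pad(values, _MAX_JUMP_BINS, constant_values=-np.inf)
        win = sliding_window_view(padded, width)
        arg = win.argmax(axis=1)
        return win[np.arange(n_bins), arg], arg + np.arange(n_bins) - _MAX_JUMP_BINS

    score_v = np.full(n_bins, -np.log(2 * n_bins)) + log_obs_v[0]
    score_u = np.full(n_bins, -np.log(2 * n_bins)) + log_obs_u[0]
    back = np.zeros((n_frames, 2 * n_bins), dtype=np.int32)

    for t in range(1, n_frames):
        mv, av = windowed_max(score_v)
        mu, au = windowed_max(score_u)

        stay_v = mv + log_stay
        from_u = score_u + log_switch
        take_stay = stay_v >= from_u
        new_v = np.where(take_stay, stay_v, from_u) + log_obs_v[t]
        back[t, :n_bins] = np.where(take_stay, av, np.arange(n_bins) + n_bins)

        stay_u = mu + log_stay
        from_v = score_v + log_switch
        take_stay_u = stay_u >= from_v
        new_u = np.where(take_stay_u, stay_u, from_v) + log_obs_u[t]
        back[t, n_bins:] = np.where(take_stay_u, au + n_bins, np.arange(n_bins))

        score_v, score_u = new_v, new_u

    full = np.concatenate([score_v, score_u])
    states = np.zeros(n_frames, dtype=np.int64)
    states[-1] = int(np.argmax(full))
    for t in range(n_frames - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def f0_stats(track: PitchTrack) -> dict[str, float]:
    """Mean/max/std/slope of F0 over voiced frames; all 0 with < 2 voiced frames.

    Slope is the least-squares slope of F0 against frame time (Hz/s).
    """
    voiced_f0 = track.f0[track.voiced]
    voiced_t = track.frame_times[track.voiced]
    if len(voiced_f0) < 2:
        return {"f0_mean": 0.0, "f0_max": 0.0, "f0_std": 0.0, "f0_slope": 0.0}
    slope = 0.0
    t_var = np.var(voiced_t)
    if t_var > _EPS:
        slope = float(np.cov(voiced_t, voiced_f0, bias=True)[0, 1] / t_var)
    return {
        "f0_mean": float(np.mean(voiced_f0)),
        "f0_max": float(np.max(voiced_f0)),
        "f0_std": float(np.std(voiced_f0)),
        "f0_slope": slope,
    }


def aci(S: Spectrogram) -> float:
    """Acoustic Complexity Index over a single temporal block.

    Per bin: sum of absolute frame-to-frame intensity change divided by the
    bin's total intensity; the index is the sum over bins.  Bins with zero
    total intensity contribute 0.
    """
    if S.n_frames < 2:
        return 0.0
    m = S.magnitudes
    num = np.abs(np.diff(m, axis=0)).sum(axis=0)
    den = m.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_bin = np.where(den > _EPS, num / np.where(den > _EPS, den, 1.0), 0.0)
    return float(per_bin.sum())


def bioacoustic_index(S: Spectrogram, band: tuple[float, float] = (2000.0, 8000.0)) -> float:
    """Area of the time-averaged dB spectrum above its in-band minimum.

    The spectrum is dB power referenced to its own maximum with a -80 dB
    floor, restricted to ``band`` (Hz); the area element is in kHz.
    """
    lo, hi = band
    nyquist = S.rate / 2.0
    if nyquist < hi:
        logger.warning("bioacoustic_index: Nyquist %.0f Hz < band top %.0f Hz, clipping", nyquist, hi)
        hi = nyquist
    mean_power = (S.magnitudes**2).mean(axis=0)
    ref = float(mean_power.max())
    if ref <= _EPS:
        return 0.0
    db = 10.0 * np.log10(np.maximum(mean_power / ref, 1e-8))  # -80 dB floor
    mask = (S.bin_freqs >= lo) & (S.bin_freqs <= hi)
    if not mask.any():
        return 0.0
    band_db = db[mask]
    df_khz = (S.bin_freqs[1] - S.bin_freqs[0]) / 1000.0
    return float(np.sum(band_db - band_db.min()) * df_khz)
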