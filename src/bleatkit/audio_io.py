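"""WAV ingestion, band-limited resampling, and clip-duration standardization.

Canonical pipeline rate is 22 050 Hz; clips are zero-padded or head-truncated
to a uniform 2.0 s so that every downstream descriptor sees the same number
of analysis frames.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

DEFAULT_RATE = 22_050
ALT_RATE = 30_000
DEFAULT_DURATION_S = 2.0


class AudioFormatError(ValueError):
    """Raised for undecodable or malformed audio input."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: float samples in [-1, 1] plus its sampling rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if int(self.rate) <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", int(self.rate))

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate


@dataclass(frozen=True)
class FrameSpec:
    """Short-time analysis geometry: window length, hop, and taper."""

    frame_length: int = 2048
    hop_length: int = 512
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.hop_length <= 0:
            raise ValueError("hop_length must be positive")
        if self.hop_length > self.frame_length:
            raise ValueError("hop_length must not exceed frame_length")


def _to_float(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; pass floats through."""
    if data.dtype.kind == "f":
        return data.astype(np.float64)
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        # scipy promotes 24-bit PCM to int32 with the payload in the top bytes
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    raise AudioFormatError(f"unsupported WAV sample dtype {data.dtype}")


def load_wav(path: str | os.PathLike) -> Waveform:
    """Read a PCM/IEEE-float WAV file as a mono waveform in [-1, 1].

    Multichannel input is averaged to mono; the rate comes from the header.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    AudioFormatError
        If the file cannot be decoded as WAV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad headers
        raise AudioFormatError(f"cannot decode {path}: {exc}") from exc
    samples = _to_float(np.atleast_1d(data))
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples=samples, rate=int(rate))


def save_wav(path: str | os.PathLike, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV (clipped to [-1, 1])."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), w.rate, pcm)


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Band-limited (polyphase) resampling to ``target_rate`` Hz.

    Output length is ``round(len * target_rate / rate)`` so the duration is
    preserved to within one sample period.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == w.rate:
        return w
    frac = Fraction(int(target_rate), int(w.rate))
    out = resample_poly(w.samples, frac.numerator, frac.denominator)
    n_target = round(len(w) * target_rate / w.rate)
    if len(out) > n_target:
        out = out[:n_target]
    elif len(out) < n_target:
        out = np.pad(out, (0, n_target - len(out)))
    return Waveform(samples=out, rate=int(target_rate))


def standardize_duration(w: Waveform, target_s: float = DEFAULT_DURATION_S) -> Waveform:
    """Zero-pad (right) or head-truncate to exactly ``round(target_s * rate)`` samples.

    Truncation keeps the clip onset: attack features (temporal centroid,
    flux) live at the front of the call.
    """
    if target_s <= 0:
        raise ValueError(f"target_s must be positive, got {target_s}")
    n_target = round(target_s * w.rate)
    if len(w) == 0:
        logger.warning("standardize_duration: empty waveform, returning silence")
        return Waveform(samples=np.zeros(n_target), rate=w.rate)
    if len(w) == n_target:
        return w
    if len(w) > n_target:
        return Waveform(samples=w.samples[:n_target], rate=w.rate)
    padded = np.pad(w.samples, (0, n_target - len(w)))
    return Waveform(samples=padded, rate=w.rate)


def scan_corpus(root: str | os.PathLike) -> Iterator[tuple[str, Path]]:
    """Yield ``(class_label, wav_path)`` for a ``<root>/<class_name>/*.wav`` layout.

    Classes and files are yielded in sorted order for determinism.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"corpus root {root} is not a directory")
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for wav_path in sorted(class_dir.glob("*.wav")):
            yield class_dir.name, wav_path


def load_corpus(root: str | os.PathLike) -> list[tuple[str, Waveform]]:
    """Load every clip under the class-per-directory layout."""
    return [(label, load_wav(path)) for label, path in scan_corpus(root)]
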