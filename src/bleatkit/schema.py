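"""Canonical ordered feature schema (156 descriptors) and full-vector extraction.

The ``table1`` schema uses per-coefficient means for the three cepstral
blocks (40 each); ``extended`` appends the 40 per-block standard deviations
(276 total) so the ``mfcc_std_*`` family exists for importance analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np

from bleatkit import cepstral, pitch_eco, spectral
from bleatkit.audio_io import FrameSpec, Waveform

N_MFCC = 40

CATEGORY_TEMPORAL = "temporal_energy"
CATEGORY_EVOLUTION = "time_evolution"
CATEGORY_MFCC = "mfcc"
CATEGORY_DELTA = "delta_mfcc"
CATEGORY_DELTA2 = "delta2_mfcc"
CATEGORY_SHAPE = "spectral_shape"
CATEGORY_COMPLEXITY = "complexity"
CATEGORY_BIOACOUSTIC = "bioacoustic"
CATEGORY_PITCH = "pitch"

SchemaMode = Literal["table1", "extended"]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered (name, category) contract for a feature vector."""

    entries: tuple[tuple[str, str], ...]
    mode: str

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def categories(self) -> list[str]:
        return [cat for _, cat in self.entries]

    def count(self, category: str) -> int:
        return sum(1 for _, cat in self.entries if cat == category)

    def to_json(self) -> str:
        return json.dumps({"mode": self.mode, "entries": list(self.entries)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        obj = json.loads(text)
        return cls(entries=tuple((n, c) for n, c in obj["entries"]), mode=obj["mode"])


def default_schema(mode: SchemaMode = "table1") -> FeatureSchema:
    """Build the canonical schema: 156 entries (table1) or 276 (extended)."""
    if mode not in ("table1", "extended"):
        raise ValueError(f"unknown schema mode {mode!r}")
    entries: list[tuple[str, str]] = []
    for name in ("rms_mean", "rms_std", "zcr_mean", "zcr_std", "autocorr_peak"):
        entries.append((name, CATEGORY_TEMPORAL))
    for name in ("flux_mean", "flux_std", "temporal_centroid"):
        entries.append((name, CATEGORY_EVOLUTION))
    for prefix, cat in (("mfcc", CATEGORY_MFCC), ("delta", CATEGORY_DELTA), ("delta2", CATEGORY_DELTA2)):
        for i in range(N_MFCC):
            entries.append((f"{prefix}_mean_{i}", cat))
    for name in ("centroid_mean", "centroid_std", "bandwidth_mean", "bandwidth_std", "rolloff_mean", "rolloff_std"):
        entries.append((name, CATEGORY_SHAPE))
    for b in range(spectral.CONTRAST_N_BANDS):
        entries.append((f"contrast_mean_{b}", CATEGORY_SHAPE))
    for b in range(spectral.CONTRAST_N_BANDS):
        entries.append((f"contrast_std_{b}", CATEGORY_SHAPE))
    entries.append(("entropy", CATEGORY_COMPLEXITY))
    entries.append(("flatness", CATEGORY_COMPLEXITY))
    entries.append(("aci", CATEGORY_BIOACOUSTIC))
    entries.append(("bioacoustic_index", CATEGORY_BIOACOUSTIC))
    for name in ("f0_mean", "f0_max", "f0_std", "f0_slope"):
        entries.append((name, CATEGORY_PITCH))
    if mode == "extended":
        for prefix, cat in (("mfcc", CATEGORY_MFCC), ("delta", CATEGORY_DELTA), ("delta2", CATEGORY_DELTA2)):
            for i in range(N_MFCC):
                entries.append((f"{prefix}_std_{i}", cat))
    return FeatureSchema(entries=tuple(entries), mode=mode)


def extract_features(
    w: Waveform,
    schema: FeatureSchema | None = None,
    spec: FrameSpec | None = None,
    fmin: float = pitch_eco.DEFAULT_FMIN,
    fmax: float = pitch_eco.DEFAULT_FMAX,
) -> np.ndarray:
    """Extract the full descriptor vector for one standardized clip.

    The waveform is expected to already be resampled and duration-
    standardized.  The result is aligned one-to-one with ``schema.names``
    and guaranteed finite.
    """
    if schema is None:
        schema = default_schema()
    if spec is None:
        spec = FrameSpec()

    S = spectral.stft(w, spec)
    values: dict[str, float] = {}
    values.update(spectral.temporal_energy_features(w, spec))
    values.update(spectral.time_evolution_features(S))
    values.update(spectral.spectral_shape_features(S))

    need_std = schema.mode == "extended"
    which = "mean_and_std" if need_std else "mean"
    C = cepstral.mfcc(S, n_coeff=N_MFCC)
    D1 = cepstral.delta(C, 1)
    D2 = cepstral.delta(C, 2)
    values.update(cepstral.cepstral_stats(C, which, prefix="mfcc"))
    values.update(cepstral.cepstral_stats(D1, which, prefix="delta"))
    values.update(cepstral.cepstral_stats(D2, which, prefix="delta2"))

    values["aci"] = pitch_eco.aci(S)
    values["bioacoustic_index"] = pitch_eco.bioacoustic_index(S)
    track = pitch_eco.pyin_track(w, fmin=fmin, fmax=fmax, spec=spec)
    values.update(pitch_eco.f0_stats(track))

    out = np.empty(len(schema))
    for i, name in enumerate(schema.names):
        if name not in values:
            raise KeyError(f"schema feature {name!r} not produced by any extractor")
        v = values[name]
        if not np.isfinite(v):
            raise ArithmeticError(f"feature {name!r} is non-finite ({v})")
        out[i] = v
    return out
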