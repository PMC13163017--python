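"""Inference latency and serialized-artifact footprint measurement."""

from __future__ import annotations

import copy
import os
import tempfile
import time
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np

from bleatkit.models import TrainedModel, predict


@dataclass(frozen=True)
class BenchResult:
    latency_ms_per_sample: float
    latency_std_ms: float
    footprint_mb: float
    repeats: int
    batch: int

    def as_dict(self) -> dict:
        return {
            "latency_ms_per_sample": self.latency_ms_per_sample,
            "latency_std_ms": self.latency_std_ms,
            "footprint_mb": self.footprint_mb,
            "repeats": self.repeats,
            "batch": self.batch,
        }


def save_bundle(m: TrainedModel, path: str | Path, scaler=None, selected=None, schema_names=None) -> int:
    """Serialize the deployable bundle (model + scaler + selection + contract).

    Returns the on-disk size in bytes — the footprint the benchmark reports.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    estimator = m.estimator
    if hasattr(estimator, "_optimizer"):
        # deployment artifact: inference needs weights, not optimizer state
        estimator = copy.copy(estimator)
        estimator._optimizer = None
        for attr in ("_best_coefs", "_best_intercepts"):
            if hasattr(estimator, attr):
                setattr(estimator, attr, None)
    bundle = {
        "spec": m.spec,
        "estimator": estimator,
        "classes": m.classes,
        "feature_names": m.feature_names,
        "scaler": scaler,
        "selected": selected,
        "schema_names": schema_names,
        "metadata": m.metadata,
    }
    joblib.dump(bundle, path, compress=0)
    return path.stat().st_size


def load_bundle(path: str | Path) -> tuple[TrainedModel, dict]:
    bundle = joblib.load(path)
    m = TrainedModel(
        spec=bundle["spec"],
        estimator=bundle["estimator"],
        classes=bundle["classes"],
        feature_names=bundle["feature_names"],
        metadata=bundle.get("metadata", {}),
    )
    extras = {k: bundle.get(k) for k in ("scaler", "selected", "schema_names")}
    return m, extras


def benchmark_model(
    m: TrainedModel,
    X_probe,
    repeats: int = 10,
    warmup: int = 2,
    bundle_path: str | Path | None = None,
) -> BenchResult:
    """Median-of-means per-sample latency plus serialized footprint.

    Warmup passes are excluded; absolute numbers are hardware-dependent and
    reported, never asserted.
    """
    X = np.asarray(X_probe, dtype=np.float64)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("probe set must be a non-empty 2-D array")
    if repeats < 3:
        raise ValueError("repeats must be >= 3")
    if not hasattr(m.estimator, "classes_"):
        raise RuntimeError("model is not fitted")

    for _ in range(warmup):
        predict(m, X)
    per_sample_ms = np.zeros(repeats)
    for r in range(repeats):
        t0 = time.perf_counter()
        predict(m, X)
        per_sample_ms[r] = (time.perf_counter() - t0) * 1000.0 / len(X)
    latency = float(np.median(per_sample_ms))
    spread = float(np.std(per_sample_ms))

    if bundle_path is None:
        with tempfile.TemporaryDirectory() as tmp:
            size = save_bundle(m, os.path.join(tmp, "model.bundle"))
    else:
        size = save_bundle(m, bundle_path)
    return BenchResult(
        latency_ms_per_sample=latency,
        latency_std_ms=spread,
        footprint_mb=size / 1_000_000.0,
        repeats=repeats,
        batch=len(X),
    )
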