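"""AHI arithmetic and the linear-regression AHI estimators.

The apnea-hypopnea index is the hourly rate of respiratory events.  The
pipeline estimates a subject's AHI not by dividing detected-event count by
time directly but by linear regression on detection summaries, which
absorbs systematic over/under-segmentation of the detector:

* 3-feature variant (3D-CNN pipeline): number of detected events, total
  duration of detected events longer than 9 s divided by sleep duration,
  and sleep duration;
* 2-feature variant (baseline): events per hour of detected-event time,
  and detected-event time as a fraction of total recording time.

"Sleep duration" is operationalized as total recording time; no sleep
staging is attempted.  Predictions are clipped below at 0, since a
negative event rate is not physical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .events import EventInterval

#: Event-duration cutoff (seconds) for the "long events" regression feature.
LONG_EVENT_CUTOFF_S = 9.0

CNN_FEATURES = ["n_events", "long_event_fraction", "sleep_duration_h"]
BASELINE_AHI_FEATURES = ["events_per_event_hour", "event_time_fraction"]

_MODEL_FEATURES = {"cnn3": CNN_FEATURES, "baseline2": BASELINE_AHI_FEATURES}


def compute_ahi(events: Sequence[EventInterval], duration_h: float) -> float:
    """Events per hour: ``|events| / duration_h``."""
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    return len(events) / duration_h


def ahi_features_cnn(events: Sequence[EventInterval], duration_h: float) -> dict:
    """The 3 regression features of the 3D-CNN pipeline."""
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    long_s = sum(e.duration_s for e in events if e.duration_s > LONG_EVENT_CUTOFF_S)
    return {
        "n_events": float(len(events)),
        "long_event_fraction": long_s / (duration_h * 3600.0),
        "sleep_duration_h": duration_h,
    }


def ahi_features_baseline(events: Sequence[EventInterval], duration_h: float) -> dict:
    """The 2 regression features of the baseline pipeline.

    Feature 1 is the detected-event count normalized by the total detected
    event duration (in hours); with no detected events it is defined as 0.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    event_h = sum(e.duration_s for e in events) / 3600.0
    return {
        "events_per_event_hour": len(events) / event_h if event_h > 0 else 0.0,
        "event_time_fraction": event_h / duration_h,
    }


@dataclass
class LinearModel:
    """Ordinary-least-squares AHI regression (with intercept)."""

    feature_names: List[str]
    coef: np.ndarray
    intercept: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "coef": list(map(float, self.coef)),
                "intercept": float(self.intercept),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(d["feature_names"], np.asarray(d["coef"], dtype=float),
                   float(d["intercept"]))


def _design(features, names) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in names if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        return features[names].to_numpy(dtype=float)
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != len(names):
        raise ValueError(
            f"feature count mismatch: expected {len(names)}, got {x.shape[1]}"
        )
    return x


def fit_ahi_regression(features, true_ahi, model: str = "baseline2") -> LinearModel:
    """Fit the AHI regression by ordinary least squares.

    ``model`` selects the published feature set (``cnn3`` or ``baseline2``).
    A rank-deficient design raises an error naming the collinear columns.
    """
    if model not in _MODEL_FEATURES:
        raise ValueError(f"unknown model variant: {model!r}")
    names = _MODEL_FEATURES[model]
    x = _design(features, names)
    y = np.asarray(true_ahi, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and true_ahi must have equal length")
    if x.shape[0] < len(names) + 1:
        raise ValueError(
            f"need at least {len(names) + 1} subjects to fit {len(names)} "
            f"features plus intercept; got {x.shape[0]}"
        )
    design = np.column_stack([np.ones(x.shape[0]), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the offending columns from the QR diagonal
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [
            (["intercept"] + names)[j]
            for j in np.flatnonzero(diag < max(tol, 1e-10))
        ]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearModel(feature_names=list(names), coef=beta[1:],
                       intercept=float(beta[0]))


def predict_ahi(model: LinearModel, features) -> np.ndarray:
    """Linear prediction clipped below at 0 (AHI cannot be negative)."""
    x = _design(features, model.feature_names)
    pred = x @ model.coef + model.intercept
    return np.maximum(pred, 0.0)
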