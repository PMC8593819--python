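"""Positional vs nonpositional sleep-apnea determination.

Sleep apnea is *positional* when the supine-position AHI is at least 50 %
higher than the nonsupine (here: lateral) AHI.  Subjects who slept in only
one position have no defined comparison and are labeled ``undetermined``
(mirroring the cohort subjects excluded for that reason in clinical
practice); a configurable minimum per-position time (default 5 minutes)
guards against unstable rates from near-zero denominators.

Besides the deterministic rule, a 3-tree random forest is provided that
predicts the label from 6 per-subject features (supine/lateral event
counts, recording times, and AHIs), matching the published classifier.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .position import PerPositionStats

logger = logging.getLogger(__name__)

#: Rule threshold: supine AHI >= 1.5x lateral AHI (boundary inclusive).
POSITIONAL_RATIO = 1.5
#: Minimum time in each position for a defined per-position AHI, hours.
MIN_POSITION_TIME_H = 5.0 / 60.0

POSITIONAL_FEATURES = [
    "supine_events", "lateral_events",
    "supine_time_h", "lateral_time_h",
    "supine_ahi", "lateral_ahi",
]

LABELS = ("positional", "nonpositional", "undetermined")


def label_positional(supine_ahi: Optional[float],
                     lateral_ahi: Optional[float]) -> str:
    """Rule-based label: positional iff supine AHI >= 1.5x lateral AHI.

    The boundary is inclusive ("at least 50 % higher").  Undefined inputs
    (``None`` or NaN, e.g. a position never slept in) yield
    ``undetermined``.
    """
    for v in (supine_ahi, lateral_ahi):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "undetermined"
    if supine_ahi < 0 or lateral_ahi < 0:
        raise ValueError("AHI values must be non-negative")
    return "positional" if supine_ahi >= POSITIONAL_RATIO * lateral_ahi else "nonpositional"


def positional_features(stats: PerPositionStats) -> dict:
    """The 6 per-subject classifier features from per-position statistics.

    AHI entries are NaN (undetermined) when the corresponding position time
    is below :data:`MIN_POSITION_TIME_H`.
    """
    sup_ok = stats.supine_time_h >= MIN_POSITION_TIME_H
    lat_ok = stats.lateral_time_h >= MIN_POSITION_TIME_H
    return {
        "supine_events": stats.supine_events,
        "lateral_events": stats.lateral_events,
        "supine_time_h": stats.supine_time_h,
        "lateral_time_h": stats.lateral_time_h,
        "supine_ahi": stats.supine_ahi if sup_ok else float("nan"),
        "lateral_ahi": stats.lateral_ahi if lat_ok else float("nan"),
    }


def _frame(features) -> pd.DataFrame:
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    missing = [c for c in POSITIONAL_FEATURES if c not in df.columns]
    if missing:
        raise KeyError(f"missing positional feature(s): {missing}")
    return df


def train_positional_rf(features, labels, n_trees: int = 3, seed: int = 0):
    """3-tree random forest over the 6 positional features.

    Undetermined subjects (single-position nights) are excluded from
    training; the exclusion count is logged.
    """
    from sklearn.ensemble import RandomForestClassifier

    df = _frame(features)
    y = np.asarray(labels, dtype=object)
    determined = np.array(
        [lab != "undetermined" for lab in y]
    ) & ~df[POSITIONAL_FEATURES].isna().any(axis=1).to_numpy()
    n_excluded = int((~determined).sum())
    if n_excluded:
        logger.info("excluding %d undetermined subject(s) from training", n_excluded)
    x = df.loc[determined, POSITIONAL_FEATURES].to_numpy(dtype=float)
    y = y[determined]
    if len(np.unique(y)) < 2:
        raise ValueError("both positional classes required for training")
    # With only 3 trees and cohort-scale sample sizes, bagging noise
    # dominates the ensemble; deterministic trees over the full feature set
    # keep the tiny forest's variance in check.
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1,
        bootstrap=False, max_features=None,
    )
    model.fit(x, y)
    return model


def predict_positional(model, features) -> List[str]:
    """Forest predictions with undetermined passthrough.

    Subjects whose per-position AHI is undefined (single-position nights)
    are returned as ``undetermined`` without consulting the model.  With
    ``model=None`` the deterministic rule is applied instead.
    """
    df = _frame(features)
    out: List[str] = []
    undet = df[POSITIONAL_FEATURES].isna().any(axis=1).to_numpy()
    x = df[POSITIONAL_FEATURES].to_numpy(dtype=float)
    for i in range(len(df)):
        if undet[i]:
            out.append("undetermined")
        elif model is None:
            out.append(label_positional(x[i, 4], x[i, 5]))
        else:
            out.append(str(model.predict(x[i : i + 1])[0]))
    return out
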