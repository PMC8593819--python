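"""Sleep-position tracking (supine vs lateral) and per-position AHI.

The position of the sleeper is classified from single video frames by a
pluggable backend, but only at the few moments where it can have changed:
once at the start of the recording and again after every gross body
movement, detected by thresholding the total displacement of the tracked
points over 1-second windows (published reference threshold: 20,000 pixels
at 640x480, scaled linearly with pixel count at other resolutions).  The
resulting labels are propagated forward into a :class:`PositionTrack` that
tiles the whole recording, from which events are attributed to positions
and per-position AHIs computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .events import EventInterval

logger = logging.getLogger(__name__)

#: Published movement threshold at the 640x480 reference resolution, pixels.
MOVEMENT_THRESHOLD_REF_PX = 20000.0
_REF_PIXEL_COUNT = 640 * 480

POSITIONS = ("supine", "lateral")


@dataclass
class PositionSegment:
    """A maximal run of constant sleeping position, ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    position: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PositionTrack:
    """Ordered position segments tiling ``[0, recording_duration_s)``."""

    segments: List[PositionSegment]
    recording_duration_s: float

    def __post_init__(self) -> None:
        t = 0.0
        for seg in self.segments:
            if abs(seg.start_s - t) > 1e-6:
                raise ValueError("segments must tile the recording without gaps")
            t = seg.end_s
        if abs(t - self.recording_duration_s) > 1e-6:
            raise ValueError("segments must cover the full recording")

    def position_at(self, t: float) -> str:
        for seg in self.segments:
            if seg.start_s <= t < seg.end_s:
                return seg.position
        return self.segments[-1].position

    def time_in(self, position: str) -> float:
        """Total seconds spent in ``position``."""
        return sum(s.duration_s for s in self.segments if s.position == position)


@dataclass
class PerPositionStats:
    supine_ahi: float
    lateral_ahi: float
    supine_time_h: float
    lateral_time_h: float
    supine_events: int
    lateral_events: int


# ---------------------------------------------------------------------------
# frame classifiers
# ---------------------------------------------------------------------------

class OraclePositionClassifier:
    """Reads the simulator's ground-truth position; for pipeline testing."""

    def __init__(self, positions: Sequence[PositionSegment]):
        self.positions = list(positions)

    def predict(self, image=None, time_s: float = 0.0) -> str:
        for seg in self.positions:
            if seg.start_s <= time_s < seg.end_s:
                return seg.position
        return self.positions[-1].position


class TrainablePositionClassifier:
    """Small image classifier fitted on simulator frames.

    A stand-in for a pretrained position CNN: frames are mean-pooled to a
    16x16 thumbnail and classified with L2-regularized logistic regression,
    which is ample for the supine/lateral shape difference.
    """

    def __init__(self, seed: int = 0, thumbnail: int = 16):
        from sklearn.linear_model import LogisticRegression

        self.thumbnail = thumbnail
        self.model = LogisticRegression(max_iter=1000, random_state=seed)

    def _features(self, images: np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        out = np.empty((images.shape[0], self.thumbnail ** 2))
        for i, img in enumerate(images):
            out[i] = resize(
                img, (self.thumbnail, self.thumbnail), anti_aliasing=True
            ).ravel()
        return out

    def fit(self, images, labels) -> "TrainablePositionClassifier":
        self.model.fit(self._features(images), np.asarray(labels))
        return self

    def predict(self, image, time_s: Optional[float] = None) -> str:
        return str(self.model.predict(self._features(image))[0])


def classify_position(frame, classifier, time_s: Optional[float] = None) -> str:
    """Supine/lateral label of a single frame from the configured backend."""
    return classifier.predict(frame, time_s=time_s)


# ---------------------------------------------------------------------------
# movement detection and track construction
# ---------------------------------------------------------------------------

def scaled_movement_threshold(height: int, width: int,
                              reference: float = MOVEMENT_THRESHOLD_REF_PX) -> float:
    """Movement threshold scaled linearly with pixel count from 640x480."""
    return reference * (height * width) / _REF_PIXEL_COUNT


def detect_large_movements(displacement, threshold: float,
                           window_s: float = 1.0) -> List[float]:
    """Window start times whose total displacement exceeds ``threshold``."""
    displacement = np.asarray(displacement, dtype=float)
    if displacement.size == 0:
        raise ValueError("displacement series is empty")
    return [float(i * window_s) for i in np.flatnonzero(displacement > threshold)]


def build_position_track(
    frames,
    movements: Sequence[float],
    classifier,
    displacement=None,
    threshold: Optional[float] = None,
    window_s: float = 1.0,
) -> PositionTrack:
    """Assign a position to every instant of the recording.

    The classifier runs on frame 0 and, after each large movement, on the
    first quiescent frame (the first following window whose displacement is
    back under the threshold, to avoid classifying mid-movement frames);
    labels are propagated forward and adjacent equal labels merged, so the
    output has no zero-length segments.
    """
    duration = frames.n_frames / frames.fps
    label0 = classifier.predict(frames.frames[0], time_s=frames.start_time)
    changes = [(0.0, label0)]
    displacement = None if displacement is None else np.asarray(displacement)
    for m in sorted(movements):
        t_q = m + window_s
        if displacement is not None and threshold is not None:
            later = np.flatnonzero(
                (np.arange(displacement.size) * window_s > m)
                & (displacement <= threshold)
            )
            if later.size:
                t_q = float(later[0] * window_s)
        t_q = min(t_q, duration - 1.0 / frames.fps)
        idx = min(int(round(t_q * frames.fps)), frames.n_frames - 1)
        label = classifier.predict(frames.frames[idx], time_s=t_q)
        if label != changes[-1][1]:
            changes.append((t_q, label))
    segments = []
    for i, (t, label) in enumerate(changes):
        end = changes[i + 1][0] if i + 1 < len(changes) else duration
        segments.append(PositionSegment(t, end, label))
    return PositionTrack(segments=segments, recording_duration_s=duration)


# ---------------------------------------------------------------------------
# per-position AHI
# ---------------------------------------------------------------------------

def per_position_ahi(events: Sequence[EventInterval],
                     track: PositionTrack) -> PerPositionStats:
    """Per-position event counts, times, and AHIs.

    Each event is attributed to the position at its *start* time.  A
    position with zero recording time has an undefined (NaN) AHI rather
    than zero.
    """
    counts = {p: 0 for p in POSITIONS}
    for ev in events:
        counts[track.position_at(ev.start_s)] += 1
    t_sup_h = track.time_in("supine") / 3600.0
    t_lat_h = track.time_in("lateral") / 3600.0
    return PerPositionStats(
        supine_ahi=counts["supine"] / t_sup_h if t_sup_h > 0 else float("nan"),
        lateral_ahi=counts["lateral"] / t_lat_h if t_lat_h > 0 else float("nan"),
        supine_time_h=t_sup_h,
        lateral_time_h=t_lat_h,
        supine_events=counts["supine"],
        lateral_events=counts["lateral"],
    )
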