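"""Motion extraction from sleep video.

This module is the bridge between raw grayscale frames and the motion
representations the rest of the pipeline consumes:

* :class:`FrameSequence` -- a stack of intensity frames with a frame rate;
* :class:`FlowSequence` -- dense per-frame-pair displacement fields
  (``dx`` side-to-side, ``dy`` up-and-down, in pixels per frame pair);
* :class:`PointTrajectories` -- sparse trajectories of points scattered on a
  uniform grid (768 by default), accumulated from per-pair flow.

Two dense-flow backends are provided.  The ``classical`` backend wraps an
iterative Lucas-Kanade estimator and is what one would run on recorded
video.  The ``exact_synthetic`` backend is an oracle: for frames produced by
the simulator it returns the analytic displacement fields of the underlying
scene, which lets every downstream stage be tested independently of flow
estimation quality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

#: Number of sparse points tracked by default.
DEFAULT_N_POINTS = 768

#: Reference resolution at which the published movement threshold is defined.
REFERENCE_RESOLUTION = (480, 640)  # (height, width)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """A time-ordered stack of grayscale frames.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)`` with finite intensities.
    fps
        Frame rate in Hz.
    start_time
        Recording time of frame 0, in seconds.
    scene
        Opaque handle to the synthetic scene that generated the frames, if
        any.  Enables the ``exact_synthetic`` flow backend and the oracle
        position classifier; ``None`` for real video.
    """

    frames: np.ndarray
    fps: float
    start_time: float = 0.0
    scene: Optional[object] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    def frame_time(self, index: int) -> float:
        """Recording time of frame ``index`` in seconds."""
        return self.start_time + index / self.fps


@dataclass
class FlowSequence:
    """Dense displacement fields between consecutive frames.

    ``fields`` has shape ``(T-1, H, W, 2)``; channel 0 is the horizontal
    displacement ``dx`` (side to side) and channel 1 the vertical ``dy``
    (up and down), both in pixels per frame pair.
    """

    fields: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields)
        if self.fields.ndim != 4 or self.fields.shape[-1] != 2:
            raise ValueError("flow fields must have shape (T-1, H, W, 2)")
        if not np.all(np.isfinite(self.fields)):
            raise ValueError("flow fields must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_fields(self) -> int:
        return self.fields.shape[0]

    @property
    def shape(self) -> tuple:
        return self.fields.shape[1:3]

    def magnitudes(self) -> np.ndarray:
        """Per-pixel L2 displacement magnitude, shape ``(T-1, H, W)``."""
        return np.sqrt(self.fields[..., 0] ** 2 + self.fields[..., 1] ** 2)


@dataclass
class PointTrajectories:
    """Trajectories of sparse tracked points.

    ``positions`` has shape ``(K, T, 2)`` in ``(x, y)`` pixel coordinates.
    """

    positions: np.ndarray
    rate: float
    origin: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 2:
            raise ValueError("positions must have shape (K, T, 2)")
        if self.origin is None:
            self.origin = self.positions[:, 0, :].copy()

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def n_samples(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def downsample(frames: FrameSequence, target_fps: float) -> FrameSequence:
    """Reduce the frame rate by keeping every ``fps/target_fps``-th frame.

    The retention starts at frame 0, so retained frame ``k`` maps to
    recording time ``k / target_fps + start_time``.  Only integer stride
    reductions are supported; no interpolation is performed.
    """
    ratio = frames.fps / target_fps
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-9:
        raise ValueError(
            f"target_fps {target_fps} does not divide source fps {frames.fps}"
        )
    return FrameSequence(
        frames=frames.frames[::step],
        fps=target_fps,
        start_time=frames.start_time,
        scene=frames.scene,
    )


def _classical_pair_flow(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """Dense flow (H, W, 2) from frame ``ref`` to ``mov`` via iterative LK."""
    from skimage.registration import optical_flow_ilk

    v, u = optical_flow_ilk(
        ref.astype(np.float32), mov.astype(np.float32), radius=7
    )
    # optical_flow_ilk returns (row, col) displacement of scene content from
    # the reference frame to the moving frame; repack as (dx, dy).
    return np.stack([u, v], axis=-1)


def dense_flow(frames: FrameSequence, backend: str = "classical") -> FlowSequence:
    """Dense optical flow between consecutive frames.

    ``backend='classical'`` runs an iterative Lucas-Kanade estimator on the
    pixel data.  ``backend='exact_synthetic'`` requires frames carrying a
    simulator scene and returns the scene's analytic flow; it is the oracle
    used to decouple downstream tests from flow-estimation error.
    """
    if frames.n_frames < 2:
        raise ValueError("dense flow requires at least 2 frames")
    if backend == "exact_synthetic":
        if frames.scene is None:
            raise ValueError(
                "exact_synthetic backend requires simulator-generated frames"
            )
        from .synthetic import exact_flow

        h, w = frames.shape
        return exact_flow(
            frames.scene.trace, frames.scene.positions, h, w, frames.fps
        )
    if backend != "classical":
        raise ValueError(f"unknown flow backend: {backend!r}")
    fields = np.empty(
        (frames.n_frames - 1,) + frames.shape + (2,), dtype=np.float32
    )
    for i in range(frames.n_frames - 1):
        fields[i] = _classical_pair_flow(frames.frames[i], frames.frames[i + 1])
    return FlowSequence(fields=fields, rate=frames.fps)


def uniform_grid(n_points: int, height: int, width: int) -> np.ndarray:
    """``(K, 2)`` array of ``(x, y)`` coordinates on a uniform grid.

    The grid aspect follows the frame aspect, e.g. 768 points on a 64x48
    frame form a 32x24 lattice.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    cols = max(1, int(round(math.sqrt(n_points * width / height))))
    rows = max(1, math.ceil(n_points / cols))
    xs = (np.arange(cols) + 0.5) * width / cols
    ys = (np.arange(rows) + 0.5) * height / rows
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
    return pts[:n_points]


def track_points(
    frames: FrameSequence,
    n_points: int = DEFAULT_N_POINTS,
    backend: str = "classical",
) -> PointTrajectories:
    """Track ``n_points`` grid-initialized points through the recording.

    Per-pair dense flow is sampled at each point's current position
    (nearest pixel) and accumulated into trajectories.  Points that leave
    the frame are re-seeded at their grid origin, keeping the point count
    constant after large movements.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if frames.n_frames < 2:
        raise ValueError("point tracking requires at least 2 frames")
    if backend == "exact_synthetic":
        if frames.scene is None:
            raise ValueError(
                "exact_synthetic backend requires simulator-generated frames"
            )
        from .synthetic import exact_point_trajectories

        h, w = frames.shape
        return exact_point_trajectories(
            frames.scene.trace, frames.scene.positions, h, w,
            rate=frames.fps, n_points=n_points,
        )

    h, w = frames.shape
    origin = uniform_grid(n_points, h, w)
    t_count = frames.n_frames
    traj = np.empty((n_points, t_count, 2), dtype=np.float64)
    traj[:, 0, :] = origin
    current = origin.copy()
    for i in range(t_count - 1):
        flow = _classical_pair_flow(frames.frames[i], frames.frames[i + 1])
        cx = np.clip(np.round(current[:, 0]).astype(int), 0, w - 1)
        cy = np.clip(np.round(current[:, 1]).astype(int), 0, h - 1)
        current = current + flow[cy, cx]
        # re-seed points that drifted out of the frame
        lost = (
            (current[:, 0] < 0) | (current[:, 0] > w - 1)
            | (current[:, 1] < 0) | (current[:, 1] > h - 1)
        )
        if np.any(lost):
            current[lost] = origin[lost]
        traj[:, i + 1, :] = current
    return PointTrajectories(positions=traj, rate=frames.fps, origin=origin)


def total_displacement(motion, window_s: float = 1.0) -> np.ndarray:
    """Total movement per non-overlapping time window, in pixels.

    For a :class:`FlowSequence` the value of window ``k`` is the sum, over
    the window's flow fields and over all pixels, of the per-pixel L2
    displacement magnitude.  For :class:`PointTrajectories` it is the sum of
    per-step L2 displacements of the tracked points -- the quantity that is
    thresholded (20,000 px at 640x480) to detect gross body movements.

    Signed components are deliberately not summed: left/right and up/down
    motion would cancel and arousals would be invisible.
    """
    if isinstance(motion, FlowSequence):
        if motion.n_fields == 0:
            raise ValueError("empty flow sequence")
        per_step = motion.magnitudes().sum(axis=(1, 2))
        rate = motion.rate
    elif isinstance(motion, PointTrajectories):
        if motion.n_samples < 2:
            raise ValueError("trajectories too short")
        steps = np.diff(motion.positions, axis=1)
        per_step = np.sqrt((steps ** 2).sum(axis=-1)).sum(axis=0)
        rate = motion.rate
    else:
        raise TypeError("motion must be a FlowSequence or PointTrajectories")
    if window_s < 1.0 / rate:
        raise ValueError("window_s must cover at least one frame pair")
    per_window = int(round(window_s * rate))
    n_windows = per_step.shape[0] // per_window
    if n_windows == 0:
        raise ValueError("recording shorter than one window")
    trimmed = per_step[: n_windows * per_window]
    return trimmed.reshape(n_windows, per_window).sum(axis=1)


def mean_endpoint_error(flow: FlowSequence, truth: np.ndarray) -> float:
    """Mean L2 error between estimated fields and a reference field array."""
    diff = flow.fields - np.asarray(truth)
    return float(np.sqrt((diff ** 2).sum(axis=-1)).mean())
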