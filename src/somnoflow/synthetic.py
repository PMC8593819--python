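"""Synthetic sleep-recording simulator.

Generates seeded, fully annotated stand-ins for overnight infrared video so
that every pipeline stage can be exercised and validated without clinical
data.  The simulator embodies the clinical event definitions the pipeline
targets:

* **apnea** -- cessation of airflow for more than 10 s; rendered as chest
  motion attenuated to 2 % of baseline (residual motion, not exactly zero);
* **hypopnea** -- airflow reduction of more than 30 % for at least 10 s;
  rendered as a uniform amplitude scale drawn from (0.3, 0.7);
* **positional apnea** -- supine AHI at least 1.5x the lateral AHI; the
  generator places events per position so the emitted ground truth
  satisfies the profile it was asked for.

Breathing is a sinusoid at a subject-specific base rate (0.2-0.4 Hz, i.e.
the ~0.5 Hz-and-below band observed during sleep) with ~10 % per-breath
amplitude jitter and a slow rate drift, plus additive white displacement
noise.  Gross body movements (position changes) appear as large lateral
shifts of the torso between position segments.

Three representations of the same scene are available and mutually
consistent: rendered intensity frames (:func:`render_frames`), analytic
dense flow (:func:`exact_flow`), and analytic point trajectories
(:func:`exact_point_trajectories`).  Time is seconds from recording start
and intervals are half-open ``[start, end)`` throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .events import EventInterval
from .motion import FrameSequence, FlowSequence, PointTrajectories, uniform_grid
from .position import PositionSegment

# -- study-condition defaults ------------------------------------------------

#: Baseline chest-displacement amplitude, pixels.  Sized for desk-scale
#: 64x48 frames: chest motion of 5-15 px at the 640x480 acquisition
#: resolution corresponds to roughly 0.5-1.5 px in a 0.1x thumbnail.
DEFAULT_AMPLITUDE_PX = 1.0
#: Additive white noise on the displacement trace, pixels.
DEFAULT_TRACE_NOISE_SD = 0.05
#: Additive pixel-intensity noise in rendered frames.
DEFAULT_FRAME_NOISE_SD = 0.02
#: Residual motion during apnea, fraction of baseline amplitude.
APNEA_RESIDUAL_SCALE = 0.02
#: Hypopnea amplitude scale range (reduction of 30-70 %).
HYPOPNEA_SCALE_RANGE = (0.3, 0.7)
#: Subject breathing-rate range, Hz.
BREATH_RATE_RANGE = (0.2, 0.4)
#: Minimum normal-breathing gap between events, seconds.
MIN_EVENT_GAP_S = 10.0
#: Supine/lateral event-rate ratio targeted for positional subjects.  The
#: defining threshold is 1.5; strongly positional patients, the clinically
#: interesting cohort for positional therapy, show near-normal nonsupine
#: rates, i.e. ratios well above the threshold.
POSITIONAL_RATE_RATIO = 6.0

_EVENT_MARGIN_START_S = 40.0  # keep events clear of recording edges
_EVENT_MARGIN_END_S = 45.0
_SEGMENT_INSET_S = 5.0  # events do not straddle position changes


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Pose:
    cy: float
    cx: float
    ay: float
    ax: float


def _pose(height: int, width: int, position: str) -> _Pose:
    if position == "supine":
        return _Pose(0.55 * height, 0.50 * width, 0.28 * height, 0.30 * width)
    if position == "lateral":
        return _Pose(0.55 * height, 0.60 * width, 0.30 * height, 0.17 * width)
    raise ValueError(f"unknown position: {position!r}")


def _band_bounds(pose: _Pose) -> Tuple[float, float]:
    """Vertical extent of the breathing (chest) band."""
    return pose.cy - pose.ay, pose.cy - 0.55 * pose.ay


def _band_mask(height: int, width: int, pose: _Pose) -> np.ndarray:
    y, x = np.mgrid[0:height, 0:width]
    y0, y1 = _band_bounds(pose)
    return (y >= y0) & (y <= y1) & (np.abs(x - pose.cx) <= 0.7 * pose.ax)


def _torso_mask(height: int, width: int, pose: _Pose) -> np.ndarray:
    y, x = np.mgrid[0:height, 0:width]
    return ((x - pose.cx) / pose.ax) ** 2 + ((y - pose.cy) / pose.ay) ** 2 <= 1.0


def _band_member(points: np.ndarray, pose: _Pose) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    y0, y1 = _band_bounds(pose)
    return (y >= y0) & (y <= y1) & (np.abs(x - pose.cx) <= 0.7 * pose.ax)


def _torso_member(points: np.ndarray, pose: _Pose) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    return ((x - pose.cx) / pose.ax) ** 2 + ((y - pose.cy) / pose.ay) ** 2 <= 1.0


@dataclass
class SyntheticScene:
    """Handle linking rendered frames back to their generating motion."""

    trace: "BreathingTrace"
    positions: List[PositionSegment]
    height: int
    width: int

    def position_at(self, t: float) -> str:
        return _segment_at(self.positions, t).position


def _segment_at(positions: Sequence[PositionSegment], t: float) -> PositionSegment:
    for seg in positions:
        if seg.start_s <= t < seg.end_s:
            return seg
    return positions[-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BreathingTrace:
    """1-D chest-displacement series in pixels.

    ``amplitude_series[k]`` is the vertical displacement of the chest at
    sample ``k / sample_rate`` seconds, relative to rest.
    """

    sample_rate: float
    amplitude_series: np.ndarray
    base_rate: float
    noise_sd: float

    def __post_init__(self) -> None:
        self.amplitude_series = np.asarray(self.amplitude_series, dtype=np.float64)
        if not np.all(np.isfinite(self.amplitude_series)):
            raise ValueError("amplitude_series must be finite")
        if not (0.05 < self.base_rate < 1.0):
            raise ValueError("base_rate must lie in (0.05, 1.0) Hz")

    @property
    def duration_s(self) -> float:
        return self.amplitude_series.shape[0] / self.sample_rate


@dataclass
class GroundTruth:
    """Simulator ground truth for one recording."""

    events: List[EventInterval]
    positions: List[PositionSegment]
    true_ahi: float
    true_supine_ahi: float
    true_lateral_ahi: float
    duration_s: float = 0.0


@dataclass
class SubjectRecord:
    """One simulated recording plus caches filled by the pipeline."""

    subject_id: str
    trace: BreathingTrace
    truth: GroundTruth
    duration_s: float
    positional_profile: str = "single_position"
    features: Optional[pd.DataFrame] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------

def _make_position_segments(rng, duration_s: float, profile: str) -> List[PositionSegment]:
    if profile == "single_position":
        return [PositionSegment(0.0, duration_s, "supine")]
    n_rolls = int(rng.integers(2, 5))
    n_seg = n_rolls + 1
    raw = 0.7 + rng.random(n_seg)
    first = str(rng.choice(["supine", "lateral"]))
    other = "lateral" if first == "supine" else "supine"
    labels = [first if i % 2 == 0 else other for i in range(n_seg)]
    # balanced nights: total supine time is 40-60 % of the recording,
    # distributed across that position's segments proportionally to raw
    supine_frac = float(rng.uniform(0.4, 0.6))
    lengths = np.empty(n_seg)
    for pos, frac in (("supine", supine_frac), ("lateral", 1.0 - supine_frac)):
        idx = [i for i, lab in enumerate(labels) if lab == pos]
        w = raw[idx] / raw[idx].sum()
        lengths[idx] = frac * duration_s * w
    segs, t = [], 0.0
    for i, ln in enumerate(lengths):
        end = duration_s if i == n_seg - 1 else t + ln
        segs.append(PositionSegment(t, end, labels[i]))
        t = end
    return segs


def _allocate_events(n: int, t_sup_h: float, t_lat_h: float, profile: str) -> Tuple[int, int]:
    """Split ``n`` events between supine and lateral to realize a profile."""
    if profile == "single_position" or t_lat_h == 0.0:
        return n, 0
    if n == 0:
        if profile == "positional":
            raise ValueError("cannot build a positional subject with 0 events")
        return 0, 0

    def ratio_positional(ns: int) -> bool:
        sup = ns / t_sup_h
        lat = (n - ns) / t_lat_h
        return sup >= 1.5 * lat

    if profile == "positional":
        r = POSITIONAL_RATE_RATIO
        ns = int(round(n * r * t_sup_h / (r * t_sup_h + t_lat_h)))
        ns = min(max(ns, 0), n)
        while ns <= n and not ratio_positional(ns):
            ns += 1
        if ns > n:
            raise ValueError("cannot satisfy positional rate ratio")
        return ns, n - ns
    if profile == "nonpositional":
        ns = int(round(n * t_sup_h / (t_sup_h + t_lat_h)))
        ns = min(max(ns, 0), n)
        while ns >= 0 and ratio_positional(ns):
            ns -= 1
        if ns < 0:
            raise ValueError(
                "cannot build a nonpositional subject: too few events for the "
                "available lateral time"
            )
        return ns, n - ns
    raise ValueError(f"unknown positional_profile: {profile!r}")


def _place_events(rng, duration_s, positions, n_by_position, event_mix=(0.5, 0.5)):
    """Draw event intervals inside position segments.

    Placement is uniform over the feasible configurations (starts uniform
    conditioned on non-overlap and >=10 s inter-event gaps), sampled
    directly via Dirichlet-distributed gaps rather than rejection, so high
    event densities remain fast and deterministic.
    """
    events: List[EventInterval] = []
    for position, n_pos in n_by_position.items():
        if n_pos == 0:
            continue
        durations = []
        labels = []
        for _ in range(n_pos):
            if rng.random() < event_mix[0]:
                labels.append("apnea")
                durations.append(float(rng.uniform(12.0, 28.0)))
            else:
                labels.append("hypopnea")
                durations.append(float(rng.uniform(12.0, 25.0)))
        segs = []
        for seg in positions:
            if seg.position != position:
                continue
            lo = max(seg.start_s + _SEGMENT_INSET_S, _EVENT_MARGIN_START_S)
            hi = min(seg.end_s - _SEGMENT_INSET_S, duration_s - _EVENT_MARGIN_END_S)
            if hi - lo > MIN_EVENT_GAP_S:
                segs.append([lo, hi, []])  # [usable lo, usable hi, events]
        if not segs:
            raise ValueError(
                f"no usable {position} segment: recording too short for the "
                f"requested events given the 10 s gap and edge margins"
            )
        # assign each event to the segment with most remaining slack
        for dur in sorted(durations, reverse=True):
            best, slack_best = None, -np.inf
            for s in segs:
                used = sum(s[2]) + MIN_EVENT_GAP_S * len(s[2])
                slack = (s[1] - s[0]) - used - dur
                if slack > slack_best:
                    best, slack_best = s, slack
            if slack_best < 0:
                raise ValueError(
                    f"duration too short to place requested events: need "
                    f"{dur:.0f}s more {position} time (10 s gaps required)"
                )
            best[2].append(dur)
        rng.shuffle(labels)
        li = 0
        for lo, hi, durs in segs:
            if not durs:
                continue
            k = len(durs)
            rng.shuffle(durs)
            free = (hi - lo) - sum(durs) - MIN_EVENT_GAP_S * (k - 1)
            gaps = rng.dirichlet(np.ones(k + 1)) * free
            t = lo + gaps[0]
            for j, dur in enumerate(durs):
                events.append(EventInterval(t, t + dur, labels[li]))
                li += 1
                t += dur + MIN_EVENT_GAP_S + gaps[j + 1]
    events.sort(key=lambda e: e.start_s)
    return events


def _synthesize_trace(rng, duration_s, events, sample_rate, amplitude_px,
                      noise_sd) -> BreathingTrace:
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    base = float(rng.uniform(*BREATH_RATE_RANGE))
    drift_phase = float(rng.uniform(0, 2 * np.pi))
    inst_rate = base * (1.0 + 0.05 * np.sin(2 * np.pi * t / 300.0 + drift_phase))
    phase = 2 * np.pi * np.cumsum(inst_rate) / sample_rate
    breath_idx = np.floor(phase / (2 * np.pi)).astype(int)
    jitter = np.exp(rng.normal(0.0, 0.1, breath_idx.max() + 1))
    env = np.ones(n)
    ramp_s = 1.0
    for ev in events:
        scale = (
            APNEA_RESIDUAL_SCALE
            if ev.label == "apnea"
            else float(rng.uniform(*HYPOPNEA_SCALE_RANGE))
        )
        i0 = int(round(ev.start_s * sample_rate))
        i1 = int(round(ev.end_s * sample_rate))
        env[i0:i1] = scale
        nr = int(round(ramp_s * sample_rate))
        if nr > 0 and i1 - i0 > 2 * nr:
            ramp = 0.5 * (1 + np.cos(np.linspace(0, np.pi, nr)))
            env[i0 : i0 + nr] = scale + (1 - scale) * ramp
            env[i1 - nr : i1] = scale + (1 - scale) * ramp[::-1]
    series = amplitude_px * jitter[breath_idx] * env * np.sin(phase)
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, n)
    return BreathingTrace(
        sample_rate=sample_rate, amplitude_series=series,
        base_rate=base, noise_sd=noise_sd,
    )


def generate_subject(
    duration_s: float,
    target_ahi: float,
    positional_profile: str = "single_position",
    seed: int = 0,
    sample_rate: float = 30.0,
    amplitude_px: float = DEFAULT_AMPLITUDE_PX,
    noise_sd: float = DEFAULT_TRACE_NOISE_SD,
    event_mix: Tuple[float, float] = (0.5, 0.5),
) -> Tuple[BreathingTrace, GroundTruth]:
    """Simulate one subject's night.

    The number of events is ``round(target_ahi * duration_s / 3600)``;
    events are non-overlapping, each longer than 10 s, separated by at
    least 10 s of normal breathing, and -- for ``positional_profile=
    'positional'`` -- distributed so the supine event rate is at least
    1.5x the lateral rate.  Identical arguments and seed give bit-identical
    output.
    """
    if duration_s < 120:
        raise ValueError("duration_s must be >= 120 s")
    if target_ahi < 0:
        raise ValueError("target_ahi must be >= 0")
    rng = np.random.default_rng(seed)
    positions = _make_position_segments(rng, duration_s, positional_profile)
    t_sup_h = sum(s.end_s - s.start_s for s in positions if s.position == "supine") / 3600.0
    t_lat_h = sum(s.end_s - s.start_s for s in positions if s.position == "lateral") / 3600.0
    n_events = int(round(target_ahi * duration_s / 3600.0))
    n_sup, n_lat = _allocate_events(n_events, t_sup_h, t_lat_h, positional_profile)
    events = _place_events(
        rng, duration_s, positions, {"supine": n_sup, "lateral": n_lat}, event_mix
    )
    trace = _synthesize_trace(
        rng, duration_s, events, sample_rate, amplitude_px, noise_sd
    )
    truth = GroundTruth(
        events=events,
        positions=positions,
        true_ahi=3600.0 * len(events) / duration_s,
        true_supine_ahi=(n_sup / t_sup_h) if t_sup_h > 0 else float("nan"),
        true_lateral_ahi=(n_lat / t_lat_h) if t_lat_h > 0 else float("nan"),
        duration_s=duration_s,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# rendering and analytic motion
# ---------------------------------------------------------------------------

def _subsampled_displacement(trace: BreathingTrace, rate: float) -> np.ndarray:
    ratio = trace.sample_rate / rate
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-9:
        raise ValueError(
            f"rate {rate} Hz must divide trace sample_rate {trace.sample_rate} Hz"
        )
    return trace.amplitude_series[::step]


def render_frames(
    trace: BreathingTrace,
    positions: Sequence[PositionSegment],
    height: int,
    width: int,
    fps: float,
    seed: int = 0,
    noise_sd: float = DEFAULT_FRAME_NOISE_SD,
) -> FrameSequence:
    """Render grayscale frames of a torso blob breathing and rolling.

    The torso is a smooth elliptical blob whose pose (shape and lateral
    offset) depends on the sleeping position; a chest ridge on its upper
    part translates vertically with the displacement trace, so the rendered
    boundary oscillates at the breathing rate.  Additive Gaussian intensity
    noise of the stated SD is applied; the output is deterministic given
    the seed.
    """
    if height < 16 or width < 16:
        raise ValueError("height and width must be >= 16")
    if fps <= 0:
        raise ValueError("fps must be positive")
    d = _subsampled_displacement(trace, fps)
    n = d.shape[0]
    rng = np.random.default_rng(seed)
    y = np.arange(height)[:, None]
    x = np.arange(width)[None, :]
    torso = {}
    for pos in ("supine", "lateral"):
        p = _pose(height, width, pos)
        q = ((x - p.cx) / p.ax) ** 2 + ((y - p.cy) / p.ay) ** 2
        torso[pos] = 0.5 * np.sqrt(np.clip(1.0 - q, 0.0, 1.0))
    frames = np.empty((n, height, width), dtype=np.float32)
    for k in range(n):
        pos = _segment_at(positions, k / fps).position
        p = _pose(height, width, pos)
        band_cy = p.cy - 0.775 * p.ay
        sy, sx = 0.12 * p.ay, 0.5 * p.ax
        bump = 0.4 * np.exp(
            -((y - (band_cy - d[k])) ** 2) / (2 * sy ** 2)
            - ((x - p.cx) ** 2) / (2 * sx ** 2)
        )
        frames[k] = 0.08 + torso[pos] + bump
    np.clip(frames, 0.0, 1.0, out=frames)
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)
    scene = SyntheticScene(trace=trace, positions=list(positions),
                           height=height, width=width)
    return FrameSequence(frames=frames, fps=fps, scene=scene)


def exact_flow(
    trace: BreathingTrace,
    positions: Sequence[PositionSegment],
    height: int,
    width: int,
    flow_rate: float,
) -> FlowSequence:
    """Analytic dense displacement fields of the synthetic scene.

    Within a position segment, pixels of the chest band move vertically by
    the trace increment; all other pixels are static.  A flow step that
    crosses a position change carries the lateral torso shift over the
    union of the two torso footprints.  This is the ground-truth oracle the
    ``exact_synthetic`` motion backend exposes, allowing downstream stages
    to be tested independently of any flow estimator.
    """
    d = _subsampled_displacement(trace, flow_rate)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to form one flow field")
    fields = np.zeros((n - 1, height, width, 2), dtype=np.float32)
    seg_starts = np.array([s.start_s for s in positions])
    t_samples = np.arange(n) / flow_rate
    seg_idx = np.clip(
        np.searchsorted(seg_starts, t_samples, side="right") - 1, 0,
        len(positions) - 1,
    )
    dd = np.diff(d)
    masks = {
        pos: _band_mask(height, width, _pose(height, width, pos))
        for pos in ("supine", "lateral")
    }
    same = seg_idx[:-1] == seg_idx[1:]
    for si in np.unique(seg_idx):
        pos = positions[si].position
        sel = np.flatnonzero(same & (seg_idx[:-1] == si))
        if sel.size:
            fields[sel[:, None], masks[pos], 1] = (-dd[sel])[:, None]
    for k in np.flatnonzero(~same):
        p_old = _pose(height, width, positions[seg_idx[k]].position)
        p_new = _pose(height, width, positions[seg_idx[k + 1]].position)
        union = _torso_mask(height, width, p_old) | _torso_mask(height, width, p_new)
        fields[k, union, 0] = p_new.cx - p_old.cx
        fields[k, union, 1] = p_new.cy - p_old.cy
    return FlowSequence(fields=fields, rate=flow_rate)


def exact_point_trajectories(
    trace: BreathingTrace,
    positions: Sequence[PositionSegment],
    height: int,
    width: int,
    rate: float,
    n_points: int = 768,
) -> PointTrajectories:
    """Analytic trajectories of grid points under the synthetic motion."""
    d = _subsampled_displacement(trace, rate)
    n = d.shape[0]
    grid = uniform_grid(n_points, height, width)
    seg_starts = np.array([s.start_s for s in positions])
    t_samples = np.arange(n) / rate
    seg_idx = np.clip(
        np.searchsorted(seg_starts, t_samples, side="right") - 1, 0,
        len(positions) - 1,
    )
    dd = np.diff(d).astype(np.float32)
    steps = np.zeros((n - 1, n_points, 2), dtype=np.float32)
    same = seg_idx[:-1] == seg_idx[1:]
    for si in np.unique(seg_idx):
        pose = _pose(height, width, positions[si].position)
        band = _band_member(grid, pose)
        sel = np.flatnonzero(same & (seg_idx[:-1] == si))
        if sel.size and band.any():
            steps[np.ix_(sel, np.flatnonzero(band))] += np.stack(
                [np.zeros_like(dd[sel]), -dd[sel]], axis=-1
            )[:, None, :]
    for k in np.flatnonzero(~same):
        p_old = _pose(height, width, positions[seg_idx[k]].position)
        p_new = _pose(height, width, positions[seg_idx[k + 1]].position)
        member = _torso_member(grid, p_old) | _torso_member(grid, p_new)
        steps[k, member, 0] += p_new.cx - p_old.cx
        steps[k, member, 1] += p_new.cy - p_old.cy
    traj = np.empty((n, n_points, 2), dtype=np.float64)
    traj[0] = grid
    np.cumsum(steps, axis=0, out=steps)
    traj[1:] = grid[None, :, :] + steps
    return PointTrajectories(
        positions=np.ascontiguousarray(traj.transpose(1, 0, 2)),
        rate=rate, origin=grid.copy(),
    )


# ---------------------------------------------------------------------------
# cohorts and annotation files
# ---------------------------------------------------------------------------

def generate_cohort(
    n_subjects: int,
    duration_s: float = 3600.0,
    ahi_range: Tuple[float, float] = (5.0, 60.0),
    profile: Union[str, Sequence[str]] = "single_position",
    seed: int = 0,
) -> List[SubjectRecord]:
    """Simulate a cohort with AHI drawn uniformly from ``ahi_range``."""
    rng = np.random.default_rng(seed)
    profiles = (
        [profile] * n_subjects if isinstance(profile, str) else list(profile)
    )
    if len(profiles) != n_subjects:
        raise ValueError("profile list length must match n_subjects")
    records = []
    for i in range(n_subjects):
        ahi = float(rng.uniform(*ahi_range))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        trace, truth = generate_subject(
            duration_s, ahi, positional_profile=profiles[i], seed=sub_seed
        )
        records.append(
            SubjectRecord(
                subject_id=f"s{i:03d}", trace=trace, truth=truth,
                duration_s=duration_s, positional_profile=profiles[i],
            )
        )
    return records


def annotations_to_frame(truth: GroundTruth, subject_id: str = "s0") -> pd.DataFrame:
    """Ground truth as a tidy annotation table.

    Columns: ``subject_id, kind{event|position}, label, start_s, end_s``.
    """
    rows = [
        (subject_id, "event", e.label, e.start_s, e.end_s) for e in truth.events
    ] + [
        (subject_id, "position", p.position, p.start_s, p.end_s)
        for p in truth.positions
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "kind", "label", "start_s", "end_s"]
    )


def frame_to_annotations(df: pd.DataFrame):
    """Inverse of :func:`annotations_to_frame` -> (events, positions)."""
    events = [
        EventInterval(r.start_s, r.end_s, r.label)
        for r in df[df["kind"] == "event"].itertuples(index=False)
    ]
    positions = [
        PositionSegment(r.start_s, r.end_s, r.label)
        for r in df[df["kind"] == "position"].itertuples(index=False)
    ]
    return events, positions
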