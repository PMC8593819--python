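"""Respiratory-event detection.

A respiratory event (apnea or hypopnea) shows up in the motion domain as a
near-cessation or marked attenuation of the quasi-periodic chest
displacement.  Two detectors are implemented:

* a 3D-convolutional network classifying stacks of 18 dense-flow images
  (from 19 consecutive frames at 2 Hz, i.e. a 9.5 s sliding window), trained
  with class-weighted cross-entropy (event:normal = 5:1), Adam, learning
  rate 1e-3, batch size 25;
* a 50-tree random forest over three hand-crafted features of the
  PCA-extracted respiratory signal (respiratory rate, movement power, total
  displacement), the previously published baseline.

Both emit per-window event probabilities; :func:`select_threshold` picks the
operating point (Youden's J over the training scores, published fallback
0.1) and :func:`scores_to_events` turns thresholded window scores back into
discrete event intervals.

The network is implemented directly on numpy (stride-tricks convolutions
with manual backpropagation and Adam), sized for CPU training at desk-scale
resolutions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

#: Flow images per classifier window (19 consecutive frames at 2 Hz).
WINDOW_FLOW_COUNT = 18
#: Time span covered by one window, seconds.
WINDOW_COVER_S = 9.5
#: Training stride inside events / outside events, seconds.
TRAIN_EVENT_STRIDE_S = 0.5
TRAIN_NORMAL_STRIDE_S = 15.0
#: Test-time stride, seconds.
TEST_STRIDE_S = 0.5
#: Published operating threshold, used as fallback for degenerate scores.
DEFAULT_THRESHOLD = 0.1
#: Class weights (normal, event) for the weighted cross-entropy loss.
DEFAULT_CLASS_WEIGHTS = (1.0, 5.0)

BASELINE_FEATURES = ["respiratory_rate", "movement_power", "total_displacement"]

_EPS = 1e-9


@dataclass
class EventInterval:
    """A detected or annotated respiratory event, ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: str = "event"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap(self, start_s: float, end_s: float) -> float:
        """Length of intersection with ``[start_s, end_s)`` in seconds."""
        return max(0.0, min(self.end_s, end_s) - max(self.start_s, start_s))


@dataclass
class WindowSample:
    """One classifier window: 18 flow fields starting at ``start_time``."""

    flow_stack: np.ndarray  # (18, H, W, 2), a view into the flow array
    start_time: float
    label: Optional[str] = None  # 'event' | 'normal' | None (test mode)
    score: Optional[float] = None


# ---------------------------------------------------------------------------
# window dataset construction
# ---------------------------------------------------------------------------

def make_windows(
    flow,
    annotations: Sequence[EventInterval] = (),
    mode: str = "train",
) -> List[WindowSample]:
    """Slice a 2 Hz flow sequence into classifier windows.

    Train mode balances the heavily skewed classes by stride: windows fully
    inside an annotated event are emitted every 0.5 s with label ``event``;
    windows fully outside all events every 15 s with label ``normal``;
    windows straddling an event boundary carry an ambiguous label and are
    discarded.  Test mode emits unlabeled windows at every 0.5 s position.

    A window starting at ``t`` covers ``[t, t + 9.5)`` seconds.  "Fully
    inside" requires the cover to sit strictly left of the event's end
    (an event region of 60 s therefore yields starts 0, 0.5, ..., 50.0).
    """
    if mode not in ("train", "test"):
        raise ValueError(f"unknown mode: {mode!r}")
    if abs(flow.rate - 2.0) > 1e-6:
        raise ValueError("classifier windows are defined on 2 Hz flow")
    n_fields = flow.n_fields
    max_index = n_fields - WINDOW_FLOW_COUNT
    if max_index < 0:
        warnings.warn("recording shorter than one window; no samples emitted")
        return []
    dt = 1.0 / flow.rate  # 0.5 s between window positions

    def window(i: int, label: Optional[str]) -> WindowSample:
        return WindowSample(
            flow_stack=flow.fields[i : i + WINDOW_FLOW_COUNT],
            start_time=i * dt,
            label=label,
        )

    if mode == "test":
        return [window(i, None) for i in range(max_index + 1)]

    samples: List[WindowSample] = []
    events = sorted(annotations, key=lambda e: e.start_s)
    for ev in events:
        i0 = int(np.ceil(ev.start_s / dt - _EPS))
        i = max(i0, 0)
        while i <= max_index and i * dt + WINDOW_COVER_S < ev.end_s - _EPS:
            samples.append(window(i, "event"))
            i += 1
    stride = int(round(TRAIN_NORMAL_STRIDE_S / dt))
    for i in range(0, max_index + 1, stride):
        t = i * dt
        outside = all(
            t + WINDOW_COVER_S <= ev.start_s + _EPS or t >= ev.end_s - _EPS
            for ev in events
        )
        if outside:
            samples.append(window(i, "normal"))
    samples.sort(key=lambda s: s.start_time)
    return samples


# ---------------------------------------------------------------------------
# numpy 3D-CNN
# ---------------------------------------------------------------------------

class _Conv3d:
    """Valid 3D convolution over (T, H, W) with C_in -> C_out channels."""

    def __init__(self, c_in, c_out, kernel, rng):
        kt, kh, kw = kernel
        fan_in = kt * kh * kw * c_in
        scale = np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0.0, scale, (kt, kh, kw, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        kt, kh, kw = self.kernel
        win = sliding_window_view(x, (kt, kh, kw), axis=(1, 2, 3))
        # win: (N, T', H', W', C, kt, kh, kw)
        self._win = win
        out = np.tensordot(win, self.w, axes=([5, 6, 7, 4], [0, 1, 2, 3]))
        return out + self.b

    def backward(self, grad):
        kt, kh, kw = self.kernel
        self.gw = np.tensordot(
            self._win, grad, axes=([0, 1, 2, 3], [0, 1, 2, 3])
        ).transpose(1, 2, 3, 0, 4).astype(np.float32)
        self.gb = grad.sum(axis=(0, 1, 2, 3)).astype(np.float32)
        # full correlation of grad with the kernel -> input gradient
        pad = [(0, 0)] + [(k - 1, k - 1) for k in self.kernel] + [(0, 0)]
        gpad = np.pad(grad, pad)
        gwin = sliding_window_view(gpad, (kt, kh, kw), axis=(1, 2, 3))
        wflip = self.w[::-1, ::-1, ::-1]
        gx = np.tensordot(gwin, wflip, axes=([5, 6, 7, 4], [0, 1, 2, 4]))
        self._win = None
        return gx.astype(np.float32)


class _Relu:
    params = ()

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class _Pool3d:
    """Max or mean pooling with fixed factors over (T, H, W); crops remainders."""

    def __init__(self, factors, op="max"):
        self.factors = factors
        self.op = op

    params = ()

    def forward(self, x):
        n = x.shape[0]
        ft, fh, fw = self.factors
        t, h, w, c = x.shape[1:]
        t2, h2, w2 = t // ft, h // fh, w // fw
        x = x[:, : t2 * ft, : h2 * fh, : w2 * fw]
        self._in_shape = (t, h, w, c)
        r = x.reshape(n, t2, ft, h2, fh, w2, fw, c)
        if self.op == "max":
            out = r.max(axis=(2, 4, 6))
            self._mask = r == out[:, :, None, :, None, :, None, :]
            self._norm = self._mask.sum(axis=(2, 4, 6), keepdims=True)
        else:
            out = r.mean(axis=(2, 4, 6))
        return out

    def backward(self, grad):
        n = grad.shape[0]
        ft, fh, fw = self.factors
        t, h, w, c = self._in_shape
        t2, h2, w2 = t // ft, h // fh, w // fw
        g = grad[:, :, None, :, None, :, None, :]
        if self.op == "max":
            r = (self._mask / self._norm) * g
            self._mask = self._norm = None
        else:
            r = np.broadcast_to(g / (ft * fh * fw),
                                (n, t2, ft, h2, fh, w2, fw, c))
        out = np.zeros((n, t, h, w, c), dtype=np.float32)
        out[:, : t2 * ft, : h2 * fh, : w2 * fw] = r.reshape(
            n, t2 * ft, h2 * fh, w2 * fw, c
        )
        return out


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        self._x = None
        return grad @ self.w.T


class EventCnn:
    """3D-convolutional event/normal classifier over flow stacks.

    The reference architecture is three conv3d(3x3x3)+ReLU+maxpool blocks
    followed by two dense layers and a softmax over {normal, event},
    parameterized by the input resolution.  Inputs wider than 32 px are
    first reduced by spatial mean pooling so that CPU training at the
    desk-scale 64x48 resolution stays tractable.

    Training follows the published recipe: Adam with initial learning rate
    0.001, batch size 25, cross-entropy weighted 5 (event) : 1 (normal).
    The epoch count is configurable; the default is sized for synthetic
    desk-scale experiments rather than full-night clinical data.
    """

    def __init__(
        self,
        input_shape,
        seed: int = 0,
        learning_rate: float = 1e-3,
        batch_size: int = 25,
        class_weights=DEFAULT_CLASS_WEIGHTS,
        epochs: int = 20,
        channels=(8, 16, 16),
        dense_units: int = 32,
    ):
        self.input_shape = tuple(input_shape)  # (T, H, W, C)
        self.seed = int(seed)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.class_weights = np.asarray(class_weights, dtype=np.float32)
        self.epochs = int(epochs)
        self.loss_history: List[float] = []
        rng = np.random.default_rng(self.seed)

        t, h, w, c = self.input_shape
        self.layers: list = []
        while h > 32 or w > 40:
            self.layers.append(_Pool3d((1, 2, 2), op="mean"))
            h, w = h // 2, w // 2
        for c_out in channels:
            k = (min(3, t), min(3, h), min(3, w))
            self.layers.append(_Conv3d(c, c_out, k, rng))
            t, h, w = t - k[0] + 1, h - k[1] + 1, w - k[2] + 1
            self.layers.append(_Relu())
            f = (2 if t >= 2 else 1, 2 if h >= 2 else 1, 2 if w >= 2 else 1)
            self.layers.append(_Pool3d(f, op="max"))
            t, h, w = t // f[0], h // f[1], w // f[2]
            c = c_out
            if t < 1 or h < 1 or w < 1:
                raise ValueError("input resolution too small for architecture")
        self._flat = t * h * w * c
        self.fc1 = _Dense(self._flat, dense_units, rng)
        self.fc2 = _Dense(dense_units, 2, rng)
        self._relu_fc = _Relu()
        self._adam_state = None
        self._rng = rng

    # -- forward / backward -------------------------------------------------

    def _forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        self._conv_shape = x.shape
        x = x.reshape(x.shape[0], -1)
        x = self._relu_fc.forward(self.fc1.forward(x))
        return self.fc2.forward(x)

    def _backward(self, grad, conv_out_shape):
        grad = self.fc1.backward(self._relu_fc.backward(self.fc2.backward(grad)))
        grad = grad.reshape(conv_out_shape)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _trainable(self):
        layers = [l for l in self.layers if getattr(l, "params", ())]
        layers += [self.fc1, self.fc2]
        return layers

    def _adam_step(self, step):
        b1, b2, eps = 0.9, 0.999, 1e-8
        if self._adam_state is None:
            self._adam_state = [
                [(np.zeros_like(p), np.zeros_like(p)) for p in l.params]
                for l in self._trainable()
            ]
        lr = self.learning_rate
        for l, state in zip(self._trainable(), self._adam_state):
            grads = [l.gw, l.gb]
            for p, g, (m, v) in zip(l.params, grads, state):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mh = m / (1 - b1 ** step)
                vh = v / (1 - b2 ** step)
                p -= lr * mh / (np.sqrt(vh) + eps)

    # -- public API ---------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray) -> "EventCnn":
        """Train on flow stacks ``x`` (N, 18, H, W, 2) with labels ``y`` in {0, 1}."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input shape {self.input_shape}, got {x.shape[1:]}"
            )
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes present")
        n = x.shape[0]
        step = 0
        for _ in range(self.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x[idx], y[idx]
                logits = self._forward(xb)
                conv_shape = self._conv_shape
                zmax = logits.max(axis=1, keepdims=True)
                ez = np.exp(logits - zmax)
                p = ez / ez.sum(axis=1, keepdims=True)
                wts = self.class_weights[yb]
                loss = -(wts * np.log(p[np.arange(len(yb)), yb] + 1e-12)).sum() / wts.sum()
                grad = p.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad *= (wts / wts.sum())[:, None]
                self._backward(grad.astype(np.float32), conv_shape)
                step += 1
                self._adam_step(step)
                epoch_loss += loss * len(yb)
            self.loss_history.append(float(epoch_loss / n))
        return self

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, column 1 = event."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        out = np.empty((x.shape[0], 2), dtype=np.float64)
        for start in range(0, x.shape[0], batch_size):
            logits = self._forward(x[start : start + batch_size])
            zmax = logits.max(axis=1, keepdims=True)
            ez = np.exp(logits - zmax)
            out[start : start + batch_size] = ez / ez.sum(axis=1, keepdims=True)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self._trainable() for p in l.params)


def _samples_to_arrays(samples: Iterable[WindowSample]):
    samples = list(samples)
    x = np.stack([s.flow_stack for s in samples]).astype(np.float32)
    labels = [s.label for s in samples]
    if any(lab is None for lab in labels):
        raise ValueError("training samples must carry labels")
    y = np.array([1 if lab == "event" else 0 for lab in labels])
    return x, y


def train_event_cnn(samples: Sequence[WindowSample], config: Optional[dict] = None,
                    seed: int = 0) -> EventCnn:
    """Train the 3D-CNN on labeled window samples (seeded, deterministic)."""
    x, y = _samples_to_arrays(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training windows")
    cfg = dict(config or {})
    model = EventCnn(input_shape=x.shape[1:], seed=seed, **cfg)
    return model.fit(x, y)


# ---------------------------------------------------------------------------
# baseline random forest
# ---------------------------------------------------------------------------

def train_event_rf(features: pd.DataFrame, labels, n_trees: int = 50,
                   seed: int = 0):
    """50-tree random forest over the three baseline features.

    Rows with undefined respiratory rate (NaN) are excluded from training
    rather than imputed.  Out-of-bag probability estimates are enabled so
    the operating threshold can be selected without in-sample optimism.
    """
    from sklearn.ensemble import RandomForestClassifier

    missing = [c for c in BASELINE_FEATURES if c not in features.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    y = np.asarray(labels)
    x = features[BASELINE_FEATURES].to_numpy(dtype=float)
    ok = ~np.isnan(x).any(axis=1)
    if not np.all(ok):
        logger.info("excluding %d windows with undefined features", (~ok).sum())
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train the classifier")
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
    )
    model.fit(x, y)
    return model


# ---------------------------------------------------------------------------
# threshold selection and interval reconstruction
# ---------------------------------------------------------------------------

def select_threshold(scores, labels, fallback: float = DEFAULT_THRESHOLD) -> float:
    """Operating threshold maximizing Youden's J on training scores.

    Candidates are midpoints between consecutive distinct score values, so
    perfectly separated classes yield the midpoint of the separating gap.
    Ties are broken toward the smallest candidate.  Degenerate score sets
    (all values equal) fall back to the published default of 0.1.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = np.array([1 if v == "event" else 0 for v in y])
    y = y.astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes required for threshold selection")
    uniq = np.unique(scores)
    if uniq.size < 2:
        warnings.warn("degenerate scores; falling back to default threshold")
        return float(fallback)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = y.sum(), (~y).sum()
    # vectorized J over candidates: positive prediction is score >= c
    pred = scores[None, :] >= candidates[:, None]
    tpr = (pred & y[None, :]).sum(axis=1) / n_pos
    fpr = (pred & ~y[None, :]).sum(axis=1) / n_neg
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[0]
    return float(candidates[best])


def scores_to_events(
    window_scores,
    threshold: float,
    min_duration_s: Optional[float] = None,
    stride_s: float = TEST_STRIDE_S,
    cover_s: float = WINDOW_COVER_S,
    merge_gap_s: float = 0.0,
    start_times=None,
) -> List[EventInterval]:
    """Reconstruct discrete event intervals from thresholded window scores.

    Each window with score >= ``threshold`` covers ``[t, t + cover_s)``;
    overlapping or near-adjacent covers (gap <= ``merge_gap_s``) are merged.
    When ``min_duration_s`` is given, merged intervals with duration <= that
    value are dropped (the duration filter the AHI features apply to events
    longer than 9 s).
    """
    scores = np.asarray(window_scores, dtype=float)
    if start_times is None:
        start_times = np.arange(scores.shape[0]) * stride_s
    else:
        start_times = np.asarray(start_times, dtype=float)
    pos = np.flatnonzero(scores >= threshold)
    intervals: List[EventInterval] = []
    for i in pos:
        t0, t1 = float(start_times[i]), float(start_times[i]) + cover_s
        s = float(scores[i])
        if intervals and t0 <= intervals[-1].end_s + merge_gap_s + _EPS:
            last = intervals[-1]
            last.end_s = max(last.end_s, t1)
            last.confidence = max(last.confidence, s)
        else:
            intervals.append(EventInterval(t0, t1, label="event", confidence=s))
    if min_duration_s is not None:
        intervals = [e for e in intervals if e.duration_s > min_duration_s]
    return intervals


# ---------------------------------------------------------------------------
# events CSV
# ---------------------------------------------------------------------------

def events_to_frame(events: Sequence[EventInterval], subject_id: str = "s0") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
            "label": [e.label for e in events],
            "confidence": [e.confidence for e in events],
        }
    )


def frame_to_events(df: pd.DataFrame) -> List[EventInterval]:
    return [
        EventInterval(r.start_s, r.end_s, getattr(r, "label", "event"),
                      getattr(r, "confidence", 1.0))
        for r in df.itertuples(index=False)
    ]
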